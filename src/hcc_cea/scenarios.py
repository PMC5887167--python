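"""Country scenarios: parameter values, ranges, and model settings.

A :class:`Scenario` bundles everything one country's analysis needs: the
base value and sensitivity range of every model parameter (monthly
transition probabilities, monthly costs in 2016 USD, state utilities), the
willingness-to-pay threshold, and the run conventions of the cohort model.
Parameters are addressed by dotted ids (``prob.tace.die_no_prog``,
``cost.sorafenib_full.initial``, ``utility.decomp`` ...); ids shared
between strategies — the post-progression mortality and decompensation
rate common to both sorafenib regimens, and the decompensated-cirrhosis
mortality common to all arms — feed every strategy that uses them, so a
sweep or a probabilistic draw moves them jointly.

The shipped ``china`` and ``usa`` files mirror the published base-case
tables field for field; costs without a published range default to
50%-200% of the base value.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .cea import incremental_table, IncrementalComparison
from .markov import (
    CEAResult,
    CohortTrace,
    CostSchedule,
    HealthState,
    ModelSpec,
    StrategyParams,
    TreatmentSchedule,
    UtilitySet,
    run_cohort,
)

__all__ = [
    "STRATEGIES",
    "ParamRange",
    "Scenario",
    "load_scenario",
    "load_builtin",
    "builtin_path",
    "write_scenario",
]

#: canonical strategy keys, in the order used throughout
STRATEGIES = ("tace", "sorafenib_full", "sorafenib_adjusted")

_DEFAULT_LABELS = {
    "tace": "TACE",
    "sorafenib_full": "Full-dose sorafenib",
    "sorafenib_adjusted": "Dose-adjusted sorafenib",
}

#: every parameter id and whether it is a probability, cost or utility
PARAMETER_IDS: dict[str, str] = {
    "prob.tace.die_no_prog": "prob",
    "prob.tace.progress": "prob",
    "prob.tace.decomp": "prob",
    "prob.tace.die_post_prog": "prob",
    "prob.sorafenib_full.die_no_prog": "prob",
    "prob.sorafenib_full.progress": "prob",
    "prob.sorafenib_adjusted.die_no_prog": "prob",
    "prob.sorafenib_adjusted.progress": "prob",
    "prob.sorafenib.decomp": "prob",
    "prob.sorafenib.die_post_prog": "prob",
    "prob.common.die_decomp": "prob",
    "cost.tace.per_session": "cost",
    "cost.sorafenib_full.initial": "cost",
    "cost.sorafenib_full.later": "cost",
    "cost.sorafenib_adjusted.initial": "cost",
    "cost.sorafenib_adjusted.later": "cost",
    "cost.state.comp_no_prog": "cost",
    "cost.state.comp_prog": "cost",
    "cost.state.decomp": "cost",
    "utility.comp_no_prog": "utility",
    "utility.comp_prog": "utility",
    "utility.decomp": "utility",
}


#: per-strategy aliases accepted as overrides (not stored in scenario files):
#: the base case assumes the two sorafenib regimens share their
#: post-progression mortality and decompensation rate, but sensitivity
#: analyses may move one arm's value on its own through these ids.
OVERRIDE_ALIASES = frozenset(
    f"prob.{s}.{slot}"
    for s in ("sorafenib_full", "sorafenib_adjusted")
    for slot in ("die_post_prog", "decomp")
)


@dataclass(frozen=True)
class ParamRange:
    """A parameter's base value and one-way sensitivity range."""

    param_id: str
    low: float
    base: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.param_id}: range must satisfy low <= base <= high, "
                f"got {self.low} <= {self.base} <= {self.high}"
            )


@dataclass
class Scenario:
    """One country's fully specified decision problem."""

    country: str
    wtp_usd_per_qaly: float
    model: ModelSpec
    values: dict[str, float]
    ranges: dict[str, ParamRange]
    labels: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_LABELS))
    tace_sessions_per_cycle: float = 1.0

    # -- parameter access -------------------------------------------------
    def parameter_ids(self) -> list[str]:
        return list(self.values)

    def value(self, param_id: str) -> float:
        self._check_id(param_id)
        return self.values[param_id]

    def range(self, param_id: str) -> ParamRange:
        self._check_id(param_id)
        return self.ranges[param_id]

    def with_value(self, param_id: str, value: float) -> "Scenario":
        """A copy of the scenario with one parameter replaced."""
        self._check_id(param_id)
        new = copy.deepcopy(self)
        new.values[param_id] = value
        return new

    def _check_id(self, param_id: str) -> None:
        if param_id not in self.values and param_id not in OVERRIDE_ALIASES:
            raise KeyError(
                f"unknown parameter {param_id!r}; valid ids: "
                f"{sorted(self.values)}"
            )

    # -- model assembly ----------------------------------------------------
    def strategy_params(
        self, strategy: str, overrides: Mapping[str, object] | None = None
    ) -> StrategyParams:
        v = dict(self.values)
        if overrides:
            v.update(overrides)
        arm = "sorafenib" if strategy.startswith("sorafenib") else strategy
        return StrategyParams(
            name=strategy,
            p_die_no_prog=v[f"prob.{strategy}.die_no_prog"],
            p_progress=v[f"prob.{strategy}.progress"],
            p_decomp=v.get(f"prob.{strategy}.decomp", v[f"prob.{arm}.decomp"]),
            p_die_post_prog=v.get(
                f"prob.{strategy}.die_post_prog", v[f"prob.{arm}.die_post_prog"]
            ),
            p_die_decomp=v["prob.common.die_decomp"],
        )

    def cost_schedule(
        self, overrides: Mapping[str, object] | None = None
    ) -> CostSchedule:
        v = dict(self.values)
        if overrides:
            v.update(overrides)
        return CostSchedule(
            country=self.country,
            state_cost={
                HealthState.COMP_NO_PROG: v["cost.state.comp_no_prog"],
                HealthState.COMP_PROG: v["cost.state.comp_prog"],
                HealthState.DECOMP: v["cost.state.decomp"],
                HealthState.DEATH: 0.0,
            },
            treatment={
                "tace": TreatmentSchedule(
                    v["cost.tace.per_session"],
                    sessions_per_cycle=self.tace_sessions_per_cycle,
                ),
                "sorafenib_full": TreatmentSchedule(
                    v["cost.sorafenib_full.initial"],
                    v["cost.sorafenib_full.later"],
                ),
                "sorafenib_adjusted": TreatmentSchedule(
                    v["cost.sorafenib_adjusted.initial"],
                    v["cost.sorafenib_adjusted.later"],
                ),
            },
        )

    def utility_set(self, overrides: Mapping[str, object] | None = None) -> UtilitySet:
        v = dict(self.values)
        if overrides:
            v.update(overrides)
        return UtilitySet(
            {
                HealthState.COMP_NO_PROG: v["utility.comp_no_prog"],
                HealthState.COMP_PROG: v["utility.comp_prog"],
                HealthState.DECOMP: v["utility.decomp"],
                HealthState.DEATH: 0.0,
            }
        )

    # -- evaluation --------------------------------------------------------
    def run(
        self, overrides: Mapping[str, object] | None = None
    ) -> dict[str, tuple[CohortTrace, CEAResult]]:
        """Run the cohort model for every strategy.

        ``overrides`` maps parameter ids to replacement values, which may be
        arrays for batch evaluation (all arrays broadcast together).
        """
        costs = self.cost_schedule(overrides)
        util = self.utility_set(overrides)
        return {
            s: run_cohort(self.model, self.strategy_params(s, overrides), costs, util)
            for s in STRATEGIES
        }

    def evaluate(
        self, overrides: Mapping[str, object] | None = None
    ) -> list[CEAResult]:
        return [res for _, res in self.run(overrides).values()]

    def incremental(self) -> list[IncrementalComparison]:
        return incremental_table(self.evaluate())

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        m = self.model
        return {
            "country": self.country,
            "wtp_usd_per_qaly": self.wtp_usd_per_qaly,
            "tace_sessions_per_cycle": self.tace_sessions_per_cycle,
            "model": {
                "cycles": m.cycles,
                "annual_discount_rate": m.annual_discount,
                "cycle_counting": m.cycle_counting,
                "discount_per_cycle": m.discount_per_cycle,
                "discount_offset": m.discount_offset,
            },
            "strategy_labels": dict(self.labels),
            "parameters": {
                pid: {
                    "base": self.values[pid],
                    "low": self.ranges[pid].low,
                    "high": self.ranges[pid].high,
                }
                for pid in self.values
            },
        }


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ValueError(f"scenario file missing field {where}.{key}")
    return mapping[key]


def _validate_value(pid: str, which: str, value: float) -> None:
    kind = PARAMETER_IDS[pid]
    path = f"parameters.{pid}.{which}"
    if kind in ("prob", "utility") and not 0.0 <= value <= 1.0:
        raise ValueError(f"{path}: {kind} value {value} outside [0, 1]")
    if kind == "cost" and value < 0:
        raise ValueError(f"{path}: cost value {value} is negative")


def scenario_from_dict(data: Mapping) -> Scenario:
    """Build and fully validate a Scenario from a parsed mapping."""
    country = _require(data, "country", "")
    wtp = float(_require(data, "wtp_usd_per_qaly", ""))
    if wtp < 0:
        raise ValueError(f"wtp_usd_per_qaly must be >= 0, got {wtp}")
    mspec = data.get("model", {})
    model = ModelSpec(
        cycles=int(mspec.get("cycles", 24)),
        annual_discount=float(mspec.get("annual_discount_rate", 0.03)),
        cycle_counting=str(mspec.get("cycle_counting", "begin")),
        discount_per_cycle=bool(mspec.get("discount_per_cycle", False)),
        discount_offset=int(mspec.get("discount_offset", 0)),
    )
    raw = _require(data, "parameters", "")
    unknown = set(raw) - set(PARAMETER_IDS)
    if unknown:
        raise ValueError(f"unknown parameter ids: {sorted(unknown)}")
    missing = set(PARAMETER_IDS) - set(raw)
    if missing:
        raise ValueError(f"scenario file missing parameters: {sorted(missing)}")

    values: dict[str, float] = {}
    ranges: dict[str, ParamRange] = {}
    for pid, kind in PARAMETER_IDS.items():
        entry = raw[pid]
        base = float(_require(entry, "base", f"parameters.{pid}"))
        _validate_value(pid, "base", base)
        if "low" in entry or "high" in entry:
            low = float(_require(entry, "low", f"parameters.{pid}"))
            high = float(_require(entry, "high", f"parameters.{pid}"))
        elif kind == "cost":
            # published convention for costs without a reported range
            low, high = 0.5 * base, 2.0 * base
        else:
            raise ValueError(f"parameters.{pid}: probability/utility needs low/high")
        _validate_value(pid, "low", low)
        _validate_value(pid, "high", high)
        values[pid] = base
        ranges[pid] = ParamRange(pid, low, base, high)

    scn = Scenario(
        country=country,
        wtp_usd_per_qaly=wtp,
        model=model,
        values=values,
        ranges=ranges,
        labels=dict(data.get("strategy_labels", _DEFAULT_LABELS)),
        tace_sessions_per_cycle=float(data.get("tace_sessions_per_cycle", 1.0)),
    )
    # exercise the component validators so structural violations surface now
    for s in STRATEGIES:
        scn.strategy_params(s)
    scn.cost_schedule()
    scn.utility_set()
    return scn


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario file (YAML)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"scenario file {path} does not contain a mapping")
    return scenario_from_dict(data)


def write_scenario(scn: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scn.to_dict(), sort_keys=False))


def builtin_path(country: str) -> Path:
    """Path to a shipped scenario file (``china`` or ``usa``)."""
    p = resources.files("hcc_cea.data") / f"{country.lower()}.yaml"
    if not p.is_file():
        raise ValueError(f"no builtin scenario {country!r}; use 'china' or 'usa'")
    return Path(str(p))


def load_builtin(country: str) -> Scenario:
    return load_scenario(builtin_path(country))
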