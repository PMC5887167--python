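"""One-way and two-way deterministic sensitivity analysis on the NMB scale.

Each parameter is moved across its sensitivity range with everything else
held at base, and the net monetary benefit of each strategy is recomputed.
Tornado entries measure, for the frontier (max-NMB) strategy, the spread of
NMB between a parameter's low and high value; crossover thresholds locate
the parameter value at which two strategies' NMBs are equal.

``effect_scale`` selects the effectiveness measure entering the NMB:

``"ly_months"``    discounted life-months (default) — the scale on which
                   the published threshold analyses are internally
                   consistent (see docs/methods.md);
``"qaly_months"``  discounted QALYs expressed in months;
``"qaly_years"``   the textbook dollars-per-QALY-year scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markov import CEAResult
from .scenarios import OVERRIDE_ALIASES, ParamRange, Scenario, STRATEGIES

__all__ = [
    "TornadoEntry",
    "EFFECT_SCALES",
    "nmb_by_strategy",
    "one_way_sweep",
    "tornado",
    "crossover_threshold",
    "two_way_grid",
]

EFFECT_SCALES = ("ly_months", "qaly_months", "qaly_years")
DEFAULT_EFFECT_SCALE = "ly_months"


def _effect(res: CEAResult, scale: str):
    if scale == "ly_months":
        return res.lyg_months
    if scale == "qaly_months":
        return 12.0 * res.qaly_years
    if scale == "qaly_years":
        return res.qaly_years
    raise ValueError(f"effect_scale must be one of {EFFECT_SCALES}, got {scale!r}")


@dataclass(frozen=True)
class TornadoEntry:
    param_id: str
    nmb_at_low: float
    nmb_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


def _as_range(scenario: Scenario, param) -> ParamRange:
    if isinstance(param, ParamRange):
        if (
            param.param_id not in scenario.values
            and param.param_id not in OVERRIDE_ALIASES
        ):
            raise KeyError(
                f"unknown parameter {param.param_id!r}; valid ids: "
                f"{sorted(scenario.values)}"
            )
        return param
    return scenario.range(param)


def nmb_by_strategy(
    scenario: Scenario,
    wtp: float | None = None,
    effect_scale: str = DEFAULT_EFFECT_SCALE,
    overrides: dict | None = None,
) -> dict[str, float | np.ndarray]:
    """NMB of every strategy at base values (plus optional overrides)."""
    wtp = scenario.wtp_usd_per_qaly if wtp is None else wtp
    out = {}
    for strategy, (_, res) in scenario.run(overrides).items():
        out[strategy] = wtp * _effect(res, effect_scale) - res.lifetime_cost
    return out


def one_way_sweep(
    scenario: Scenario,
    param,
    n_points: int = 11,
    wtp: float | None = None,
    effect_scale: str = DEFAULT_EFFECT_SCALE,
) -> pd.DataFrame:
    """NMB of each strategy as one parameter moves across its range.

    Returns a tidy frame with the parameter value and one NMB column per
    strategy.  All other parameters stay at base, so a degenerate range
    gives constant curves equal to the base-case NMB.
    """
    pr = _as_range(scenario, param)
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    grid = np.linspace(pr.low, pr.high, n_points)
    curves = nmb_by_strategy(
        scenario, wtp, effect_scale, overrides={pr.param_id: grid}
    )
    frame = pd.DataFrame({pr.param_id: grid})
    for s in STRATEGIES:
        frame[s] = curves[s]
    return frame


def tornado(
    scenario: Scenario,
    params: list | None = None,
    wtp: float | None = None,
    effect_scale: str = DEFAULT_EFFECT_SCALE,
    per_strategy: str | None = None,
) -> list[TornadoEntry]:
    """Tornado entries, sorted by descending bar width.

    By default each bar reports the NMB of the frontier (argmax-NMB)
    strategy at the parameter's low and high value; pass ``per_strategy``
    to track one strategy's own NMB instead.
    """
    if params is None:
        params = [scenario.range(pid) for pid in scenario.parameter_ids()]
    if not params:
        raise ValueError("tornado requires at least one parameter")

    def frontier(value_overrides):
        curves = nmb_by_strategy(scenario, wtp, effect_scale, value_overrides)
        if per_strategy is not None:
            return float(curves[per_strategy])
        return float(max(curves.values()))

    entries = []
    for p in params:
        pr = _as_range(scenario, p)
        entries.append(
            TornadoEntry(
                pr.param_id,
                frontier({pr.param_id: pr.low}),
                frontier({pr.param_id: pr.high}),
            )
        )
    # descending width; ties broken by id so the order is input-invariant
    return sorted(entries, key=lambda e: (-e.bar_width, e.param_id))


def crossover_threshold(
    scenario: Scenario,
    param,
    strategies: tuple[str, str],
    wtp: float | None = None,
    effect_scale: str = DEFAULT_EFFECT_SCALE,
    rtol: float = 1e-6,
) -> float | None:
    """Parameter value at which two strategies' NMBs are equal.

    Bisection (Brent) between the range ends to relative tolerance
    ``rtol``; returns None when the NMB difference does not change sign
    over the range.
    """
    pr = _as_range(scenario, param)
    a, b = strategies
    if a not in STRATEGIES or b not in STRATEGIES:
        raise ValueError(f"strategies must be among {STRATEGIES}, got {strategies}")

    def gap(v: float) -> float:
        curves = nmb_by_strategy(scenario, wtp, effect_scale, {pr.param_id: v})
        return float(curves[a] - curves[b])

    if pr.low == pr.high:
        return None
    g_lo, g_hi = gap(pr.low), gap(pr.high)
    if g_lo == 0.0 and g_hi == 0.0:
        return None  # identical curves, no crossing
    if g_lo == 0.0:
        return pr.low
    if g_hi == 0.0:
        return pr.high
    if np.sign(g_lo) == np.sign(g_hi):
        return None
    return float(brentq(gap, pr.low, pr.high, rtol=max(rtol, 4e-16)))


def two_way_grid(
    scenario: Scenario,
    param_a,
    param_b,
    resolution: int | tuple[int, int] = 101,
    wtp: float | None = None,
    effect_scale: str = DEFAULT_EFFECT_SCALE,
    strategies: tuple[str, ...] = STRATEGIES,
) -> pd.DataFrame:
    """Optimal strategy over a grid of two parameters.

    Returns a tidy frame (param_a value, param_b value, optimal_strategy).
    ``strategies`` can restrict the comparison, e.g. to TACE vs full-dose
    sorafenib only.
    """
    pa, pb = _as_range(scenario, param_a), _as_range(scenario, param_b)
    if pa.param_id == pb.param_id:
        raise ValueError(f"two_way_grid needs distinct parameters, got {pa.param_id!r} twice")
    if isinstance(resolution, int):
        resolution = (resolution, resolution)
    na, nb = resolution
    ga = np.linspace(pa.low, pa.high, na) if na > 1 else np.array([pa.base])
    gb = np.linspace(pb.low, pb.high, nb) if nb > 1 else np.array([pb.base])
    A, B = np.meshgrid(ga, gb, indexing="ij")
    curves = nmb_by_strategy(
        scenario, wtp, effect_scale, overrides={pa.param_id: A, pb.param_id: B}
    )
    stack = np.stack([np.broadcast_to(curves[s], A.shape) for s in strategies], axis=-1)
    best = np.argmax(stack, axis=-1)
    return pd.DataFrame(
        {
            pa.param_id: A.ravel(),
            pb.param_id: B.ravel(),
            "optimal_strategy": [strategies[i] for i in best.ravel()],
        }
    )
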