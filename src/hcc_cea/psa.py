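"""Probabilistic sensitivity analysis: sampling, CEAC, ICER intervals.

Every parameter with a sensitivity range receives a sampling distribution
— gamma for costs, beta for probabilities and utilities — parameterised by
the method of moments so that the mean equals the base-case value and the
standard deviation is the range width treated as a 95% interval,
``sd = (high - low) / (2 * z_0.975)``.  Parameters are sampled
independently; ids shared between strategies are drawn once per replicate
so the strategies move jointly.  Sampled exits from the progression-free
state are renormalised only when a draw violates the sum <= 1 constraint;
such draws are counted and reported.

The cost-effectiveness acceptability curve (CEAC) reports, at each
willingness-to-pay, the fraction of replicates in which each strategy has
the strictly highest net monetary benefit (ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scenarios import PARAMETER_IDS, Scenario, STRATEGIES
from .sensitivity import DEFAULT_EFFECT_SCALE, _effect

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "fit_distribution",
    "scenario_distributions",
    "run_psa",
    "ceac",
    "icer_summary",
    "default_wtp_grid",
]

_Z95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution derived from (base, low, high).

    ``family`` is ``"beta"``, ``"gamma"`` or ``"point"`` (degenerate range);
    ``a``/``b`` are alpha/beta for the beta family and shape/scale for the
    gamma family.  The mean equals ``base`` by construction.
    """

    param_id: str
    family: str
    a: float
    b: float
    base: float
    low: float
    high: float

    @property
    def mean(self) -> float:
        if self.family == "point":
            return self.base
        if self.family == "beta":
            return self.a / (self.a + self.b)
        return self.a * self.b

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.base)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size)
        return rng.gamma(self.a, self.b, size)


def fit_distribution(
    base: float, low: float, high: float, family: str, param_id: str = ""
) -> DistributionSpec:
    """Method-of-moments beta or gamma spec with mean = base.

    The (low, high) range is treated as a 95% interval, so
    ``sd = (high - low) / (2 * 1.959964)``.  A degenerate range yields a
    point mass.  Beta requires base strictly inside (0, 1) unless the range
    is degenerate; the implied variance must be admissible.
    """
    if not low <= base <= high:
        raise ValueError(
            f"{param_id or 'parameter'}: need low <= base <= high, "
            f"got {low}, {base}, {high}"
        )
    if family not in ("beta", "gamma"):
        raise ValueError(f"family must be 'beta' or 'gamma', got {family!r}")
    if low == high:
        return DistributionSpec(param_id, "point", 0.0, 0.0, base, low, high)
    sd = (high - low) / (2.0 * _Z95)
    var = sd * sd
    if family == "beta":
        if not 0.0 < base < 1.0:
            raise ValueError(
                f"{param_id or 'parameter'}: beta family needs base in (0, 1), "
                f"got {base}"
            )
        if var >= base * (1.0 - base):
            raise ValueError(
                f"{param_id or 'parameter'}: implied variance {var:.4g} too "
                f"large for a beta with mean {base}"
            )
        nu = base * (1.0 - base) / var - 1.0
        return DistributionSpec(
            param_id, "beta", base * nu, (1.0 - base) * nu, base, low, high
        )
    if base <= 0:
        raise ValueError(
            f"{param_id or 'parameter'}: gamma family needs base > 0, got {base}"
        )
    return DistributionSpec(
        param_id, "gamma", base * base / var, var / base, base, low, high
    )


def family_for(param_id: str) -> str:
    """Gamma for costs, beta for probabilities and utilities."""
    return "gamma" if PARAMETER_IDS.get(param_id) == "cost" else "beta"


def scenario_distributions(scenario: Scenario) -> dict[str, DistributionSpec]:
    return {
        pid: fit_distribution(
            r.base, r.low, r.high, family_for(pid), param_id=pid
        )
        for pid, r in ((p, scenario.range(p)) for p in scenario.parameter_ids())
    }


@dataclass
class PSAResult:
    """Replicated model outcomes plus the sampled parameter vectors."""

    scenario_country: str
    seed: int
    n_draws: int
    params: pd.DataFrame  # one row per draw, one column per parameter id
    samples: pd.DataFrame  # long: draw, strategy, cost, qaly_years, lyg_months
    n_clipped: dict[str, int] = field(default_factory=dict)

    def wide(self, column: str) -> pd.DataFrame:
        """Draw-by-strategy matrix of one outcome column."""
        return self.samples.pivot(index="draw", columns="strategy", values=column)


def run_psa(scenario: Scenario, n_draws: int, seed: int) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Each replicate draws one joint parameter vector and runs the cohort
    model for all strategies.  Fully reproducible from ``seed``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    dists = scenario_distributions(scenario)
    sampled = {pid: dists[pid].sample(rng, n_draws) for pid in sorted(dists)}

    # renormalise competing exits from the progression-free state per strategy
    n_clipped: dict[str, int] = {}
    overrides = dict(sampled)
    for s in STRATEGIES:
        arm = "sorafenib" if s.startswith("sorafenib") else s
        die = overrides[f"prob.{s}.die_no_prog"]
        prog = overrides[f"prob.{s}.progress"]
        dec = overrides[f"prob.{arm}.decomp"]
        total = die + prog + dec
        bad = total > 1.0
        n_clipped[s] = int(np.count_nonzero(bad))
        if n_clipped[s]:
            scale = np.where(bad, 1.0 / total, 1.0)
            overrides[f"prob.{s}.die_no_prog"] = die * scale
            overrides[f"prob.{s}.progress"] = prog * scale
            overrides[f"prob.{arm}.decomp"] = dec * scale

    rows = []
    for s, (_, res) in scenario.run(overrides).items():
        rows.append(
            pd.DataFrame(
                {
                    "draw": np.arange(n_draws),
                    "strategy": s,
                    "cost": res.lifetime_cost,
                    "qaly_years": res.qaly_years,
                    "lyg_months": res.lyg_months,
                }
            )
        )
    return PSAResult(
        scenario_country=scenario.country,
        seed=seed,
        n_draws=n_draws,
        params=pd.DataFrame(sampled),
        samples=pd.concat(rows, ignore_index=True),
        n_clipped=n_clipped,
    )


def default_wtp_grid() -> np.ndarray:
    """$0 to $100,000 in $500 steps — covers both countries' thresholds."""
    return np.arange(0.0, 100_000.0 + 1.0, 500.0)


def ceac(
    result: PSAResult,
    wtp_grid: np.ndarray | None = None,
    effect_scale: str = DEFAULT_EFFECT_SCALE,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    One row per willingness-to-pay with the probability each strategy has
    the highest NMB (ties split equally); probabilities sum to 1.
    """
    if result.samples.empty:
        raise ValueError("ceac requires a non-empty PSA result")
    wtp_grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if wtp_grid.size == 0:
        raise ValueError("ceac requires a non-empty WTP grid")
    cost = result.wide("cost")[list(STRATEGIES)].to_numpy()
    if effect_scale == "qaly_years":
        eff = result.wide("qaly_years")[list(STRATEGIES)].to_numpy()
    elif effect_scale == "qaly_months":
        eff = 12.0 * result.wide("qaly_years")[list(STRATEGIES)].to_numpy()
    elif effect_scale == "ly_months":
        eff = result.wide("lyg_months")[list(STRATEGIES)].to_numpy()
    else:
        raise ValueError(f"unknown effect_scale {effect_scale!r}")

    rows = []
    for w in wtp_grid:
        nmb = w * eff - cost
        best = nmb.max(axis=1, keepdims=True)
        win = nmb == best
        share = win / win.sum(axis=1, keepdims=True)
        rows.append(share.mean(axis=0))
    out = pd.DataFrame(rows, columns=list(STRATEGIES))
    out.insert(0, "wtp", wtp_grid)
    return out


def icer_summary(
    result: PSAResult,
    reference: str = "sorafenib_adjusted",
    de_tol: float = 1e-9,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Median and central interval of per-draw pairwise ICERs.

    ICERs are (comparator - reference) cost over QALY differences, in
    dollars per QALY-year.  Draws with |deltaQALY| below ``de_tol`` have no
    defined ratio and are counted separately.
    """
    if result.n_draws < 2:
        raise ValueError("icer_summary requires at least two draws")
    if reference not in STRATEGIES:
        raise ValueError(f"unknown reference strategy {reference!r}")
    cost = result.wide("cost")
    qaly = result.wide("qaly_years")
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    rows = []
    for s in STRATEGIES:
        if s == reference:
            continue
        dc = (cost[s] - cost[reference]).to_numpy()
        de = (qaly[s] - qaly[reference]).to_numpy()
        defined = np.abs(de) > de_tol
        icers = dc[defined] / de[defined]
        rows.append(
            {
                "comparator": s,
                "reference": reference,
                "median_icer": float(np.median(icers)) if icers.size else np.nan,
                "icer_lo": float(np.quantile(icers, lo_q)) if icers.size else np.nan,
                "icer_hi": float(np.quantile(icers, hi_q)) if icers.size else np.nan,
                "n_defined": int(defined.sum()),
                "n_undefined": int((~defined).sum()),
            }
        )
    return pd.DataFrame(rows)
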