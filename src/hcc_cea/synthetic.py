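"""Seed-deterministic synthetic inputs for every stage of the analysis.

Three generators mirror the statistical structure the analysis assumes:
study-level event counts under a random-effects binomial model
(heterogeneity injected on the arcsine scale, where the pooling model is
correctly specified), exponential survival cohorts consistent with the
constant-hazard conversion of medians to monthly probabilities, and fully
random — but always valid — model scenarios for fuzzing the cohort engine
and the decision metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rates import StudyProportion
from .scenarios import ParamRange, Scenario, load_builtin, STRATEGIES

__all__ = [
    "SyntheticStudySet",
    "gen_study_set",
    "gen_survival_cohort",
    "gen_scenario",
]


@dataclass(frozen=True)
class SyntheticStudySet:
    """Specification of a heterogeneous set of proportion studies.

    Per study the transformed mean ``2*asin(sqrt(true_p))`` is perturbed by
    a normal deviate with sd ``tau`` before binomial counts are drawn.
    """

    true_p: float
    tau: float
    k: int
    n_per_study: int | list[int]
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_p <= 1.0:
            raise ValueError(f"true_p must lie in [0, 1], got {self.true_p}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


def gen_study_set(spec: SyntheticStudySet) -> list[StudyProportion]:
    """Binomial counts with between-study heterogeneity on the arcsine scale."""
    rng = np.random.default_rng(spec.seed)
    ns = (
        [spec.n_per_study] * spec.k
        if isinstance(spec.n_per_study, int)
        else list(spec.n_per_study)
    )
    if len(ns) != spec.k:
        raise ValueError(f"n_per_study has {len(ns)} entries for k={spec.k}")
    theta = 2.0 * math.asin(math.sqrt(spec.true_p))
    th = np.clip(rng.normal(theta, spec.tau, spec.k), 0.0, math.pi)
    ps = np.sin(th / 2.0) ** 2
    return [
        StudyProportion(int(rng.binomial(n, p)), int(n)) for n, p in zip(ns, ps)
    ]


def gen_survival_cohort(
    median_months: float, n: int, seed: int
) -> np.ndarray:
    """Exponential event times (months) with the given median survival."""
    if median_months <= 0:
        raise ValueError(f"median_months must be positive, got {median_months}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.exponential(median_months / math.log(2.0), n)


def gen_scenario(seed: int) -> Scenario:
    """A random but fully valid three-strategy scenario.

    Probabilities are drawn inside ranges that keep every competing-exit
    sum well below 1, utilities are ordered by disease severity, and each
    parameter gets a +/-20% sensitivity range (clipped to validity), so the
    result passes full scenario validation for use in property tests.
    """
    rng = np.random.default_rng(seed)
    scn = load_builtin("china")
    v = scn.values

    for s in STRATEGIES:
        v[f"prob.{s}.die_no_prog"] = rng.uniform(0.02, 0.30)
        v[f"prob.{s}.progress"] = rng.uniform(0.02, 0.30)
    v["prob.tace.decomp"] = rng.uniform(0.0, 0.08)
    v["prob.sorafenib.decomp"] = rng.uniform(0.0, 0.08)
    v["prob.tace.die_post_prog"] = rng.uniform(0.05, 0.40)
    v["prob.sorafenib.die_post_prog"] = rng.uniform(0.05, 0.40)
    v["prob.common.die_decomp"] = rng.uniform(0.05, 0.40)

    for pid in list(v):
        if pid.startswith("cost."):
            v[pid] = v[pid] * rng.uniform(0.3, 2.0)
    u_c = rng.uniform(0.60, 0.90)
    u_p = rng.uniform(0.40, u_c)
    v["utility.comp_no_prog"] = u_c
    v["utility.comp_prog"] = u_p
    v["utility.decomp"] = rng.uniform(0.30, u_p)

    scn.country = f"synthetic-{seed}"
    scn.wtp_usd_per_qaly = rng.uniform(5_000.0, 100_000.0)
    for pid, base in v.items():
        kind_cap = 1.0 if not pid.startswith("cost.") else np.inf
        low = max(0.0, 0.8 * base)
        high = min(kind_cap, 1.2 * base) if np.isfinite(kind_cap) else 1.2 * base
        scn.ranges[pid] = ParamRange(pid, low, base, max(base, high))
    # revalidate the assembled components
    for s in STRATEGIES:
        scn.strategy_params(s)
    scn.cost_schedule()
    scn.utility_set()
    return scn
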