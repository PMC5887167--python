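"""Derivation of monthly transition probabilities and meta-analytic pooling.

Published survival summaries (median overall survival, time to progression)
are converted to per-cycle probabilities under a constant-hazard assumption:
the declining exponential approximation of life expectancy (DEALE).  With
exponential survival and median ``m`` months, the monthly hazard is
``ln 2 / m`` and the one-month event probability ``1 - exp(-ln 2 / m)``.

Study-level proportions (events / total) are pooled on the Freeman-Tukey
double-arcsine scale, which stabilises the binomial variance and admits
zero-event studies, with DerSimonian-Laird random-effects weights and
Miller's back-transformation to the proportion scale.  Wilson score
intervals are used for per-study confidence limits because they cannot
extend below zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SurvivalSummary",
    "StudyProportion",
    "PooledEstimate",
    "deale_monthly_prob",
    "prob_to_median",
    "double_arcsine",
    "double_arcsine_variance",
    "double_arcsine_back",
    "wilson_ci",
    "pool_random_effects",
    "read_study_table",
    "write_pooled_estimate",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SurvivalSummary:
    """A published median survival (months), optionally with a range."""

    median_months: float
    range_low_months: float | None = None
    range_high_months: float | None = None

    def __post_init__(self) -> None:
        if self.median_months <= 0:
            raise ValueError(
                f"median_months must be positive, got {self.median_months}"
            )
        lo, hi = self.range_low_months, self.range_high_months
        if lo is not None and hi is not None and not lo <= self.median_months <= hi:
            raise ValueError(
                "survival range must bracket the median: "
                f"{lo} <= {self.median_months} <= {hi} fails"
            )

    def monthly_prob(self) -> float:
        return deale_monthly_prob(self.median_months)

    def monthly_prob_range(self) -> tuple[float, float] | None:
        """Monthly-probability range; note longer survival means lower risk."""
        if self.range_low_months is None or self.range_high_months is None:
            return None
        return (
            deale_monthly_prob(self.range_high_months),
            deale_monthly_prob(self.range_low_months),
        )


@dataclass(frozen=True)
class StudyProportion:
    """Event count out of a study total, e.g. deaths within one month."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"total must be positive, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"events must lie in [0, total], got {self.events}/{self.total}"
            )

    @property
    def proportion(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class PooledEstimate:
    """Random-effects pooled proportion with its 95% interval.

    ``tau_sq`` is the between-study variance on the double-arcsine scale.
    """

    pooled_p: float
    ci_low: float
    ci_high: float
    tau_sq: float
    k: int
    t_pooled: float
    se_t: float


def deale_monthly_prob(median_months):
    """Monthly event probability implied by a median survival in months.

    ``p = 1 - exp(-ln 2 / median)``: exactly half the cohort has the event
    by the median under exponential survival, so a 1-month median gives 0.5.
    Accepts scalars or arrays; strictly decreasing in the median.
    """
    if isinstance(median_months, SurvivalSummary):
        median_months = median_months.median_months
    m = np.asarray(median_months, dtype=float)
    if np.any(m <= 0) or not np.all(np.isfinite(m)):
        raise ValueError(f"median_months must be positive, got {median_months!r}")
    p = -np.expm1(-_LN2 / m)
    return float(p) if np.ndim(median_months) == 0 else p


def prob_to_median(p):
    """Median survival (months) implied by a monthly probability: the exact
    inverse of :func:`deale_monthly_prob`, defined on (0, 1)."""
    q = np.asarray(p, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError(f"monthly probability must lie strictly in (0, 1), got {p!r}")
    m = _LN2 / -np.log1p(-q)
    return float(m) if np.ndim(p) == 0 else m


def double_arcsine(sp: StudyProportion | tuple[int, int]) -> float:
    """Freeman-Tukey double-arcsine transform of an observed proportion.

    ``t = asin(sqrt(x/(n+1))) + asin(sqrt((x+1)/(n+1)))`` in radians,
    finite on [0, pi] and defined for x = 0 and x = n.
    """
    sp = _as_study(sp)
    x, n = sp.events, sp.total
    return math.asin(math.sqrt(x / (n + 1))) + math.asin(math.sqrt((x + 1) / (n + 1)))


def double_arcsine_variance(total: float) -> float:
    """Sampling variance of the double-arcsine transform, ``1 / (n + 0.5)``."""
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    return 1.0 / (total + 0.5)


def double_arcsine_back(t: float, n_eff: float) -> float:
    """Miller's back-transformation of a double-arcsine value to a proportion.

    ``n_eff`` is the effective sample size (the study n, or for a pooled
    value the harmonic mean of study sizes).  Values of ``t`` below the
    transform of 0 events (above that of n events) map to 0 (1).
    """
    if not 0.0 <= t <= math.pi:
        raise ValueError(f"transformed value must lie in [0, pi], got {t}")
    if n_eff <= 0:
        raise ValueError(f"n_eff must be positive, got {n_eff}")
    # attainable range of the transform at this sample size
    t0 = math.asin(math.sqrt(1.0 / (n_eff + 1.0)))
    if t <= t0:
        return 0.0
    if t >= math.pi - t0:
        return 1.0
    s = math.sin(t)
    inner = s + (s - 1.0 / s) / n_eff
    p = 0.5 * (1.0 - math.copysign(1.0, math.cos(t)) * math.sqrt(1.0 - inner * inner))
    return min(1.0, max(0.0, p))


def wilson_ci(
    sp: StudyProportion | tuple[int, int], conf: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Bounds are clipped to [0, 1]; the lower bound is exactly 0 for zero
    events and the upper bound exactly 1 when every subject has the event.
    """
    sp = _as_study(sp)
    if not 0.0 < conf < 1.0:
        raise ValueError(f"conf must lie strictly in (0, 1), got {conf}")
    low, high = proportion_confint(sp.events, sp.total, alpha=1 - conf, method="wilson")
    low = 0.0 if sp.events == 0 else max(0.0, float(low))
    high = 1.0 if sp.events == sp.total else min(1.0, float(high))
    return low, high


def pool_random_effects(
    studies: Iterable[StudyProportion | tuple[int, int]], conf: float = 0.95
) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling on the double-arcsine scale.

    Inverse-variance weights ``1/(1/(n_i + 0.5) + tau^2)``; the pooled value
    and its normal-theory interval are back-transformed with the harmonic
    mean of the study sizes as the effective n.
    """
    studies = [_as_study(s) for s in studies]
    if not studies:
        raise ValueError("pool_random_effects requires at least one study")
    if not 0.0 < conf < 1.0:
        raise ValueError(f"conf must lie strictly in (0, 1), got {conf}")
    k = len(studies)
    t = np.array([double_arcsine(s) for s in studies])
    v = np.array([double_arcsine_variance(s.total) for s in studies])
    w = 1.0 / v
    t_fixed = float(np.sum(w * t) / np.sum(w))
    if k == 1:
        tau_sq = 0.0
    else:
        q = float(np.sum(w * (t - t_fixed) ** 2))
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau_sq = max(0.0, (q - (k - 1)) / c)
    w_star = 1.0 / (v + tau_sq)
    t_pooled = float(np.sum(w_star * t) / np.sum(w_star))
    se = float(math.sqrt(1.0 / np.sum(w_star)))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    n_eff = k / float(np.sum(1.0 / np.array([s.total for s in studies])))
    lo_t = min(max(t_pooled - z * se, 0.0), math.pi)
    hi_t = min(max(t_pooled + z * se, 0.0), math.pi)
    return PooledEstimate(
        pooled_p=double_arcsine_back(min(max(t_pooled, 0.0), math.pi), n_eff),
        ci_low=double_arcsine_back(lo_t, n_eff),
        ci_high=double_arcsine_back(hi_t, n_eff),
        tau_sq=tau_sq,
        k=k,
        t_pooled=t_pooled,
        se_t=se,
    )


def read_study_table(path: str | Path) -> list[StudyProportion]:
    """Read study-level proportions from a delimited table with columns
    ``study_id``, ``events``, ``total`` (separator inferred)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"events", "total"} - set(df.columns)
    if missing:
        raise ValueError(f"study table {path} lacks required columns: {sorted(missing)}")
    return [
        StudyProportion(int(row.events), int(row.total)) for row in df.itertuples()
    ]


def write_pooled_estimate(est: PooledEstimate, path: str | Path) -> None:
    """Write a pooled estimate as JSON (or CSV if the suffix is .csv)."""
    path = Path(path)
    record = {
        "pooled_p": est.pooled_p,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "tau_sq": est.tau_sq,
        "k": est.k,
    }
    if path.suffix.lower() == ".csv":
        pd.DataFrame([record]).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(record, indent=2) + "\n")


def _as_study(sp) -> StudyProportion:
    if isinstance(sp, StudyProportion):
        return sp
    return StudyProportion(*sp)
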