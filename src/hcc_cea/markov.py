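"""Four-state Markov cohort engine with cycle-dependent rewards.

The model follows a cohort of advanced hepatocellular carcinoma patients
through four health states — compensated cirrhosis without progression,
compensated cirrhosis with progression, decompensated cirrhosis, and death
— in one-month cycles.  Competing monthly exits from the progression-free
state (death, tumour progression, decompensation) combine additively on
the probability scale; progressed and decompensated patients receive no
further active treatment and can only die or remain.  Death is absorbing.

Rewards (life-months, quality-adjusted life-years, costs) accrue per cycle
from state occupancy.  Three counting conventions are supported:

``begin``  occupancy at the start of the cycle (before the transition);
``end``    occupancy after the transition;
``half``   the mean of the two — the usual half-cycle correction.

Discounting supports the textbook form ``(1+r)^(-t/12)`` for an annual
rate ``r`` and monthly cycles, and a per-cycle form ``(1+r)^(-t)`` in
which the annual rate is applied to every cycle.  The per-cycle form, with
the first cycle undiscounted and half-cycle counting, is the convention
under which the published base case is reproduced (see the shipped
scenario files and docs/methods.md); class defaults are the textbook ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "HealthState",
    "StrategyParams",
    "TreatmentSchedule",
    "CostSchedule",
    "UtilitySet",
    "ModelSpec",
    "CohortTrace",
    "CEAResult",
    "discount_factor",
    "transition_matrix",
    "transition_row",
    "run_cohort",
]


class HealthState(IntEnum):
    """The four health states; the integer value indexes matrices."""

    COMP_NO_PROG = 0
    COMP_PROG = 1
    DECOMP = 2
    DEATH = 3


_ALIVE = (HealthState.COMP_NO_PROG, HealthState.COMP_PROG, HealthState.DECOMP)


def _np(x):
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class StrategyParams:
    """Monthly transition probabilities for one treatment strategy.

    Fields may be scalars or equally shaped arrays (for batch evaluation,
    e.g. probabilistic sensitivity analysis).  ``p_background`` is an
    additive all-cause mortality applied in every living state; the source
    analysis treats it as negligible at age 60 and it defaults to 0.
    """

    name: str
    p_die_no_prog: float
    p_progress: float
    p_decomp: float
    p_die_post_prog: float
    p_die_decomp: float
    p_background: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for fname in (
            "p_die_no_prog",
            "p_progress",
            "p_decomp",
            "p_die_post_prog",
            "p_die_decomp",
            "p_background",
        ):
            v = _np(getattr(self, fname))
            if np.any((v < 0) | (v > 1)):
                raise ValueError(
                    f"strategy {self.name!r}: {fname} must lie in [0, 1]"
                )
        exit_sum = (
            _np(self.p_die_no_prog)
            + _np(self.p_progress)
            + _np(self.p_decomp)
            + _np(self.p_background)
        )
        if np.any(exit_sum > 1.0 + 1e-12):
            raise ValueError(
                f"strategy {self.name!r}: competing monthly exits from the "
                "progression-free state (death + progression + decompensation "
                f"+ background) sum to {np.max(exit_sum):.4f} > 1"
            )
        for fname in ("p_die_post_prog", "p_die_decomp"):
            v = _np(getattr(self, fname)) + _np(self.p_background)
            if np.any(v > 1.0 + 1e-12):
                raise ValueError(
                    f"strategy {self.name!r}: {fname} + background mortality "
                    "exceeds 1"
                )

    @property
    def batch_shape(self) -> tuple[int, ...]:
        return np.broadcast_shapes(
            *(
                np.shape(getattr(self, f))
                for f in (
                    "p_die_no_prog",
                    "p_progress",
                    "p_decomp",
                    "p_die_post_prog",
                    "p_die_decomp",
                    "p_background",
                )
            )
        )


def transition_matrix(sp: StrategyParams) -> np.ndarray:
    """The one-cycle transition matrix, shape ``batch_shape + (4, 4)``."""
    shape = sp.batch_shape
    die_c = np.broadcast_to(_np(sp.p_die_no_prog) + _np(sp.p_background), shape)
    prog = np.broadcast_to(_np(sp.p_progress), shape)
    dec = np.broadcast_to(_np(sp.p_decomp), shape)
    die_p = np.broadcast_to(_np(sp.p_die_post_prog) + _np(sp.p_background), shape)
    die_d = np.broadcast_to(_np(sp.p_die_decomp) + _np(sp.p_background), shape)
    zero = np.zeros(shape)
    one = np.ones(shape)
    rows = [
        [1.0 - die_c - prog - dec, prog, dec, die_c],
        [zero, 1.0 - die_p, zero, die_p],
        [zero, zero, 1.0 - die_d, die_d],
        [zero, zero, zero, one],
    ]
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def transition_row(sp: StrategyParams, state: HealthState) -> dict[HealthState, float]:
    """The transition distribution out of one state (scalar parameters)."""
    if sp.batch_shape != ():
        raise ValueError("transition_row requires scalar strategy parameters")
    m = transition_matrix(sp)
    return {HealthState(j): float(m[state, j]) for j in range(4)}


@dataclass(frozen=True)
class TreatmentSchedule:
    """Cycle-dependent monthly treatment cost for one strategy.

    Sorafenib strategies pay ``initial_usd_per_month`` for the first
    ``switch_after_cycle`` cycles and ``later_usd_per_month`` afterwards
    (the patient-assistance programme price).  TACE is priced per session;
    ``sessions_per_cycle`` scales a per-session price into a monthly cost
    (default one session per monthly cycle while progression-free).
    """

    initial_usd_per_month: float
    later_usd_per_month: float | None = None
    switch_after_cycle: int = 3
    sessions_per_cycle: float = 1.0

    def cost_at(self, cycle: int):
        if cycle < 1:
            raise ValueError(f"cycle index starts at 1, got {cycle}")
        later = (
            self.initial_usd_per_month
            if self.later_usd_per_month is None
            else self.later_usd_per_month
        )
        price = self.initial_usd_per_month if cycle <= self.switch_after_cycle else later
        return self.sessions_per_cycle * _np(price)

    def by_cycle(self, cycles: int) -> dict[int, float]:
        return {t: float(self.cost_at(t)) for t in range(1, cycles + 1)}


@dataclass(frozen=True)
class CostSchedule:
    """Monthly costs (2016 USD) by health state plus per-strategy treatment.

    ``state_cost`` covers disease management in each living state; active
    treatment cost applies only while progression-free and is looked up by
    strategy name in ``treatment``.  Death costs nothing.
    """

    country: str
    state_cost: dict[HealthState, float]
    treatment: dict[str, TreatmentSchedule]

    def __post_init__(self) -> None:
        for s in _ALIVE:
            if s not in self.state_cost:
                raise ValueError(f"state_cost missing {s.name} for {self.country}")
            if np.any(_np(self.state_cost[s]) < 0):
                raise ValueError(f"state_cost[{s.name}] must be non-negative")
        if np.any(_np(self.state_cost.get(HealthState.DEATH, 0.0)) != 0.0):
            raise ValueError("DEATH must cost 0")

    def treatment_cost(self, strategy: str, cycle: int):
        if strategy not in self.treatment:
            raise KeyError(
                f"no treatment schedule for {strategy!r}; "
                f"known: {sorted(self.treatment)}"
            )
        return self.treatment[strategy].cost_at(cycle)

    def treatment_cost_by_cycle(self, strategy: str, cycles: int) -> dict[int, float]:
        return self.treatment[strategy].by_cycle(cycles)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights (QALY per year of occupancy)."""

    utility: dict[HealthState, float]

    def __post_init__(self) -> None:
        for s in _ALIVE:
            if s not in self.utility:
                raise ValueError(f"utility missing state {s.name}")
            if np.any((_np(self.utility[s]) < 0) | (_np(self.utility[s]) > 1)):
                raise ValueError(f"utility[{s.name}] must lie in [0, 1]")
        if np.any(_np(self.utility.get(HealthState.DEATH, 0.0)) != 0.0):
            raise ValueError("DEATH utility must be 0")

    def vector(self, shape: tuple[int, ...] = ()) -> np.ndarray:
        u = np.zeros(shape + (4,))
        for s in _ALIVE:
            u[..., s] = self.utility[s]
        return u


@dataclass(frozen=True)
class ModelSpec:
    """Run-length, discounting and counting conventions of the cohort model.

    Defaults are the textbook conventions (begin-cycle counting, annual
    discounting applied as ``(1+r)^(-t/12)``).  ``discount_per_cycle=True``
    applies the annual rate to every monthly cycle and ``discount_offset=1``
    leaves the first cycle undiscounted; the shipped scenario files enable
    those together with half-cycle counting to reproduce the published
    analysis (see docs/methods.md).
    """

    cycles: int = 24
    cycle_length_months: float = 1.0
    annual_discount: float = 0.03
    initial_distribution: dict[HealthState, float] | None = None
    cycle_counting: str = "begin"
    discount_per_cycle: bool = False
    discount_offset: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError(f"cycles must be >= 1, got {self.cycles}")
        if self.annual_discount < 0:
            raise ValueError(f"annual_discount must be >= 0, got {self.annual_discount}")
        if self.cycle_counting not in ("begin", "half", "end"):
            raise ValueError(
                f"cycle_counting must be 'begin', 'half' or 'end', "
                f"got {self.cycle_counting!r}"
            )
        if self.initial_distribution is not None:
            tot = sum(self.initial_distribution.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"initial distribution sums to {tot}, not 1")

    @property
    def half_cycle_correction(self) -> bool:
        return self.cycle_counting == "half"

    def initial_vector(self) -> np.ndarray:
        x = np.zeros(4)
        if self.initial_distribution is None:
            x[HealthState.COMP_NO_PROG] = 1.0
        else:
            for s, p in self.initial_distribution.items():
                x[HealthState(s)] = p
        return x


def discount_factor(
    cycle: int,
    annual_rate: float,
    *,
    per_cycle: bool = False,
    offset: int = 0,
) -> float:
    """Discount factor for a 1-month cycle (cycle indices start at 1).

    Textbook form: ``(1+r)^(-(cycle-offset)/12)``.  With ``per_cycle=True``
    the annual rate compounds every cycle: ``(1+r)^(-(cycle-offset))``.
    """
    if cycle < 1:
        raise ValueError(f"cycle index starts at 1, got {cycle}")
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    exponent = float(cycle - offset)
    if not per_cycle:
        exponent /= 12.0
    return (1.0 + annual_rate) ** (-exponent)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted reward streams.

    ``occupancy`` has shape ``(cycles+1, 4)`` (row 0 is the initial
    distribution) — or ``batch + (cycles+1, 4)`` for batch runs.  The
    reward vectors are already discounted and use the counting convention
    of the run.
    """

    occupancy: np.ndarray
    per_cycle_ly: np.ndarray
    per_cycle_qaly: np.ndarray
    per_cycle_cost: np.ndarray


@dataclass(frozen=True)
class CEAResult:
    """Lifetime discounted totals for one strategy."""

    strategy: str
    lifetime_cost: float
    lyg_months: float
    qaly_years: float


def run_cohort(
    spec: ModelSpec,
    sp: StrategyParams,
    costs: CostSchedule,
    util: UtilitySet,
) -> tuple[CohortTrace, CEAResult]:
    """Run the cohort model for one strategy and accumulate rewards.

    Per cycle ``t`` (1-based) with counting weight ``w`` and discount
    ``d(t)``: life-months add ``sum(w[alive]) * d``, QALYs add
    ``sum(w[s] * u[s]) / 12 * d`` and costs add state costs plus the
    strategy's treatment cost (progression-free state only), weighted the
    same way.  All parameter fields may be arrays; results broadcast.
    """
    shape = np.broadcast_shapes(
        sp.batch_shape,
        np.shape(costs.treatment_cost(sp.name, 1)),
        np.shape(costs.treatment_cost(sp.name, spec.cycles)),
        *(np.shape(costs.state_cost[s]) for s in _ALIVE),
        *(np.shape(util.utility[s]) for s in _ALIVE),
    )
    T = np.broadcast_to(transition_matrix(sp), shape + (4, 4))
    x = np.broadcast_to(spec.initial_vector(), shape + (4,)).copy()

    u = util.vector(shape)
    state_cost = np.zeros(shape + (4,))
    for s in _ALIVE:
        state_cost[..., s] = costs.state_cost[s]

    occ = np.empty(shape + (spec.cycles + 1, 4))
    occ[..., 0, :] = x
    ly = np.empty(shape + (spec.cycles,))
    qaly = np.empty(shape + (spec.cycles,))
    cost = np.empty(shape + (spec.cycles,))

    for t in range(1, spec.cycles + 1):
        x_next = np.einsum("...i,...ij->...j", x, T)
        if spec.cycle_counting == "begin":
            w = x
        elif spec.cycle_counting == "end":
            w = x_next
        else:
            w = 0.5 * (x + x_next)
        d = discount_factor(
            t,
            spec.annual_discount,
            per_cycle=spec.discount_per_cycle,
            offset=spec.discount_offset,
        )
        treat = np.broadcast_to(costs.treatment_cost(sp.name, t), shape)
        ly[..., t - 1] = w[..., :3].sum(axis=-1) * spec.cycle_length_months * d
        qaly[..., t - 1] = (w * u).sum(axis=-1) / 12.0 * spec.cycle_length_months * d
        cost[..., t - 1] = (
            (w * state_cost).sum(axis=-1) + w[..., HealthState.COMP_NO_PROG] * treat
        ) * d
        x = x_next
        occ[..., t, :] = x

    trace = CohortTrace(occ, ly, qaly, cost)
    tot_c, tot_l, tot_q = cost.sum(axis=-1), ly.sum(axis=-1), qaly.sum(axis=-1)
    if shape == ():
        result = CEAResult(sp.name, float(tot_c), float(tot_l), float(tot_q))
    else:
        result = CEAResult(sp.name, tot_c, tot_l, tot_q)
    return trace, result
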