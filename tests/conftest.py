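"""Shared fixtures: scenario objects and the individual-level oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hcc_cea.markov import HealthState, transition_matrix
from hcc_cea.scenarios import load_builtin

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def china():
    return load_builtin("china")


@pytest.fixture(scope="session")
def usa():
    return load_builtin("usa")


def simulate_individuals(spec, sp, costs, util, n, seed):
    """Monte Carlo random walks through the Markov model, one row per
    patient, accumulating the same discounted rewards as the cohort engine.

    Independent of the cohort code path: transitions are sampled per
    patient and rewards follow the counting convention explicitly.
    Returns per-patient (ly, qaly, cost) arrays.
    """
    rng = np.random.default_rng(seed)
    cum = np.cumsum(transition_matrix(sp), axis=1)
    state = np.zeros(n, dtype=np.int64)
    u = util.vector()
    sc = np.array(
        [float(costs.state_cost[HealthState(i)]) for i in range(3)] + [0.0]
    )
    ly = np.zeros(n)
    qaly = np.zeros(n)
    cost = np.zeros(n)
    for t in range(1, spec.cycles + 1):
        nxt = (rng.random(n)[:, None] > cum[state]).sum(axis=1)
        d = (1.0 + spec.annual_discount) ** (
            -(t - spec.discount_offset) / (1.0 if spec.discount_per_cycle else 12.0)
        )
        treat = float(costs.treatment_cost(sp.name, t))

        def rewards(st):
            alive = (st < 3).astype(float)
            return alive, u[st], sc[st] + treat * (st == 0)

        lb, ub, cb = rewards(state)
        le, ue, ce = rewards(nxt)
        if spec.cycle_counting == "begin":
            L, U, C = lb, ub, cb
        elif spec.cycle_counting == "end":
            L, U, C = le, ue, ce
        else:
            L, U, C = 0.5 * (lb + le), 0.5 * (ub + ue), 0.5 * (cb + ce)
        ly += L * spec.cycle_length_months * d
        qaly += U / 12.0 * d
        cost += C * d
        state = nxt
    return ly, qaly, cost


@pytest.fixture(scope="session")
def individual_simulator():
    return simulate_individuals
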