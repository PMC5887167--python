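"""Cohort engine: transition structure, rewards, discounting, oracle."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcc_cea.markov import (
    CostSchedule,
    HealthState,
    ModelSpec,
    StrategyParams,
    TreatmentSchedule,
    UtilitySet,
    discount_factor,
    run_cohort,
    transition_matrix,
    transition_row,
)

C, P, D, X = HealthState


def make_costs(state=(0.0, 0.0, 0.0), treat=0.0, name="tace"):
    return CostSchedule(
        country="test",
        state_cost={C: state[0], P: state[1], D: state[2], X: 0.0},
        treatment={name: TreatmentSchedule(treat)},
    )


def make_utils(u=(1.0, 1.0, 1.0)):
    return UtilitySet({C: u[0], P: u[1], D: u[2], X: 0.0})


prob = st.floats(0.0, 0.3)
strategy_st = st.builds(
    lambda a, b, c, d, e: StrategyParams("tace", a, b, c, d, e),
    prob, prob, prob, st.floats(0.0, 0.9), st.floats(0.0, 0.9),
)


class TestTransitions:
    def test_zero_hazards_identity(self):
        sp = StrategyParams("tace", 0, 0, 0, 0, 0)
        assert np.allclose(transition_matrix(sp), np.eye(4))

    def test_full_dose_base_case_row(self):
        sp = StrategyParams("sorafenib_full", 0.069, 0.1319, 0.009, 0.1399, 0.19)
        row = transition_row(sp, C)
        assert row[X] == pytest.approx(0.069)
        assert row[P] == pytest.approx(0.1319)
        assert row[D] == pytest.approx(0.009)
        assert row[C] == pytest.approx(0.7901)

    def test_certain_post_progression_death(self):
        sp = StrategyParams("tace", 0.1, 0.1, 0.1, 1.0, 0.2)
        row = transition_row(sp, P)
        assert row[X] == 1.0 and row[P] == 0.0

    def test_death_is_absorbing(self):
        sp = StrategyParams("tace", 0.1, 0.1, 0.1, 0.2, 0.2)
        assert transition_row(sp, X) == {C: 0.0, P: 0.0, D: 0.0, X: 1.0}

    def test_competing_exits_over_one_rejected_naming_strategy(self):
        with pytest.raises(ValueError, match="sorafenib_full"):
            StrategyParams("sorafenib_full", 0.5, 0.4, 0.2, 0.1, 0.1)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match="p_progress"):
            StrategyParams("tace", 0.1, 1.2, 0.0, 0.1, 0.1)

    @given(strategy_st)
    def test_rows_sum_to_one(self, sp):
        m = transition_matrix(sp)
        assert np.allclose(m.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(m >= -1e-15)


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        assert discount_factor(7, 0.0) == 1.0

    def test_annual_closed_form(self):
        assert discount_factor(12, 0.03) == pytest.approx(1.0 / 1.03)
        assert discount_factor(24, 0.03) == pytest.approx(0.9426, abs=1e-4)

    def test_per_cycle_and_offset(self):
        assert discount_factor(1, 0.03, per_cycle=True, offset=1) == 1.0
        assert discount_factor(2, 0.03, per_cycle=True, offset=1) == pytest.approx(
            1.0 / 1.03
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="annual_rate"):
            discount_factor(1, -0.01)
        with pytest.raises(ValueError, match="cycle"):
            discount_factor(0, 0.03)

    @given(st.integers(1, 48), st.floats(0.0, 0.2))
    def test_monotone_non_increasing(self, t, r):
        assert discount_factor(t + 1, r) <= discount_factor(t, r) <= 1.0


class TestCohortRewards:
    def test_immortal_cohort_conserves_time(self):
        """No mortality, utility 1, no discounting: 24 undiscounted
        months and exactly 2 QALYs."""
        spec = ModelSpec(annual_discount=0.0)
        sp = StrategyParams("tace", 0, 0, 0, 0, 0)
        _, res = run_cohort(spec, sp, make_costs(), make_utils())
        assert res.lyg_months == pytest.approx(24.0, abs=1e-12)
        assert res.qaly_years == pytest.approx(2.0, abs=1e-12)

    def test_certain_first_cycle_death_yields_one_month(self):
        spec = ModelSpec(annual_discount=0.0)
        sp = StrategyParams("tace", 1.0, 0, 0, 0, 0)
        _, res = run_cohort(spec, sp, make_costs(), make_utils())
        assert res.lyg_months == pytest.approx(1.0, abs=1e-12)

    def test_china_base_case_qalys(self, china):
        """The published base case: 0.375 / 0.435 / 0.482 QALYs for
        TACE / full-dose / dose-adjusted."""
        got = {s: r.qaly_years for s, (_, r) in china.run().items()}
        assert got["tace"] == pytest.approx(0.375, abs=0.01)
        assert got["sorafenib_full"] == pytest.approx(0.435, abs=0.01)
        assert got["sorafenib_adjusted"] == pytest.approx(0.482, abs=0.01)

    @given(strategy_st, st.sampled_from(["begin", "half", "end"]))
    @settings(max_examples=40)
    def test_occupancy_conservation_and_death_monotone(self, sp, counting):
        spec = ModelSpec(cycle_counting=counting)
        trace, _ = run_cohort(spec, sp, make_costs(), make_utils())
        assert np.allclose(trace.occupancy.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(np.diff(trace.occupancy[:, X]) >= -1e-12)

    @given(strategy_st)
    @settings(max_examples=40)
    def test_discount_free_identity_qaly_equals_ly(self, sp):
        spec = ModelSpec(annual_discount=0.0)
        _, res = run_cohort(spec, sp, make_costs(), make_utils())
        assert 12.0 * res.qaly_years == pytest.approx(res.lyg_months, rel=1e-12)

    def test_mortality_increase_never_helps(self, china):
        base = {s: r for s, (_, r) in china.run().items()}
        worse = china.with_value("prob.tace.die_no_prog", 0.2).run()
        assert worse["tace"][1].lyg_months < base["tace"].lyg_months
        assert worse["tace"][1].qaly_years < base["tace"].qaly_years

    def test_cost_increase_never_cheapens(self, china):
        base = {s: r for s, (_, r) in china.run().items()}
        dearer = china.with_value("cost.tace.per_session", 5000.0).run()
        assert dearer["tace"][1].lifetime_cost > base["tace"].lifetime_cost

    def test_batch_run_matches_scalar_runs(self, china):
        grid = np.array([0.08, 0.115, 0.13])
        batch = china.run({"prob.tace.die_no_prog": grid})["tace"][1]
        for i, v in enumerate(grid):
            scalar = china.with_value("prob.tace.die_no_prog", float(v)).run()
            r = scalar["tace"][1]
            assert batch.qaly_years[i] == pytest.approx(r.qaly_years, rel=1e-12)
            assert batch.lifetime_cost[i] == pytest.approx(r.lifetime_cost, rel=1e-12)

    def test_treatment_cost_switch_after_three_cycles(self):
        sched = TreatmentSchedule(100.0, 1.0, switch_after_cycle=3)
        assert [float(sched.cost_at(t)) for t in (1, 2, 3, 4, 24)] == [
            100.0,
            100.0,
            100.0,
            1.0,
            1.0,
        ]

    def test_cohort_matches_individual_simulation(self, china, individual_simulator):
        """Deterministic cohort totals equal the mean of 100,000
        individual random walks within 3 standard errors."""
        sp = china.strategy_params("tace")
        costs, util = china.cost_schedule(), china.utility_set()
        _, det = run_cohort(china.model, sp, costs, util)
        ly, qaly, cost = individual_simulator(china.model, sp, costs, util, 100_000, 7)
        n = len(ly)
        for sim, expect in ((ly, det.lyg_months), (qaly, det.qaly_years), (cost, det.lifetime_cost)):
            z = (sim.mean() - expect) / (sim.std() / np.sqrt(n))
            assert abs(z) < 3.0


class TestComponentValidation:
    def test_death_state_must_be_free_and_valueless(self):
        with pytest.raises(ValueError, match="DEATH"):
            CostSchedule("t", {C: 1.0, P: 1.0, D: 1.0, X: 5.0}, {})
        with pytest.raises(ValueError, match="DEATH"):
            UtilitySet({C: 0.7, P: 0.6, D: 0.5, X: 0.3})

    def test_utility_bounds(self):
        with pytest.raises(ValueError, match="COMP_NO_PROG"):
            UtilitySet({C: 1.2, P: 0.6, D: 0.5, X: 0.0})

    def test_model_spec_validation(self):
        with pytest.raises(ValueError, match="cycle_counting"):
            ModelSpec(cycle_counting="middle")
        with pytest.raises(ValueError, match="initial distribution"):
            ModelSpec(initial_distribution={C: 0.5})
        assert ModelSpec(cycle_counting="half").half_cycle_correction
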