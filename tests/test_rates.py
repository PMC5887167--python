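"""Survival-to-probability conversion, transforms, intervals, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from hcc_cea.rates import (
    PooledEstimate,
    StudyProportion,
    SurvivalSummary,
    deale_monthly_prob,
    double_arcsine,
    double_arcsine_back,
    double_arcsine_variance,
    pool_random_effects,
    prob_to_median,
    read_study_table,
    wilson_ci,
    write_pooled_estimate,
)

# every published table row that prints both the source median (or time to
# progression) in months and the derived monthly rate in percent
PRINTED_DERIVED_ROWS = [
    (9.7, 6.90),
    (4.9, 13.19),
    (9.2, 7.26),
    (4.6, 13.99),
    (15.0, 4.52),
    (12.0, 5.61),
    (6.4, 10.26),
    (1.8, 31.96),
    (6.0, 10.91),
    (9.5, 7.04),
    (4.7, 13.71),
    (1.9, 30.57),
    (3.3, 18.95),
    (2.7, 22.64),
]


class TestDeale:
    @pytest.mark.parametrize("median,percent", PRINTED_DERIVED_ROWS)
    def test_reproduces_printed_monthly_rates(self, median, percent):
        """Constant-hazard conversion matches every printed derived rate
        to the 2 printed decimal places."""
        assert round(100.0 * deale_monthly_prob(median), 2) == pytest.approx(percent)

    def test_median_one_month_gives_one_half(self):
        assert deale_monthly_prob(1.0) == pytest.approx(0.5, abs=1e-12)

    def test_long_survival_limit(self):
        assert deale_monthly_prob(1e9) == pytest.approx(0.0, abs=1e-6)

    def test_rejects_non_positive_median(self):
        with pytest.raises(ValueError, match="median_months"):
            deale_monthly_prob(0.0)
        with pytest.raises(ValueError, match="median_months"):
            deale_monthly_prob(-3.0)

    @given(
        st.floats(min_value=0.1, max_value=500.0),
        st.floats(min_value=0.1, max_value=500.0),
    )
    def test_strictly_decreasing_in_median(self, m1, m2):
        if m1 == m2:
            return
        lo, hi = sorted([m1, m2])
        assert deale_monthly_prob(lo) > deale_monthly_prob(hi)

    @given(st.floats(min_value=0.05, max_value=1000.0))
    def test_prob_to_median_is_exact_inverse(self, median):
        p = deale_monthly_prob(median)
        assert prob_to_median(p) == pytest.approx(median, rel=1e-12)
        assert deale_monthly_prob(prob_to_median(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize(
        "p,median", [(0.5, 1.0), (0.0690, 9.70), (0.1319, 4.90)]
    )
    def test_prob_to_median_examples(self, p, median):
        assert prob_to_median(p) == pytest.approx(median, abs=0.01)

    def test_prob_to_median_rejects_boundary(self):
        for p in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                prob_to_median(p)

    def test_survival_summary_validation_and_range(self):
        s = SurvivalSummary(9.7, 3.3, 9.7)
        lo, hi = s.monthly_prob_range()
        # longer survival -> lower monthly risk, so range ends swap
        assert lo == pytest.approx(deale_monthly_prob(9.7))
        assert hi == pytest.approx(deale_monthly_prob(3.3))
        with pytest.raises(ValueError, match="median"):
            SurvivalSummary(-1.0)
        with pytest.raises(ValueError, match="range"):
            SurvivalSummary(10.0, 1.0, 5.0)


class TestDoubleArcsine:
    def test_zero_event_study(self):
        # asin(0) + asin(sqrt(1/11)), direct numeric evaluation
        expected = math.asin(math.sqrt(1.0 / 11.0))
        assert double_arcsine((0, 10)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3064, abs=5e-4)

    def test_symmetry_point_is_half_pi(self):
        # x/(n+1) and (x+1)/(n+1) are complementary at x = n/2
        assert double_arcsine((5, 10)) == pytest.approx(math.pi / 2, abs=1e-12)

    @given(st.integers(0, 200), st.integers(1, 200))
    def test_reflection_symmetry_and_bounds(self, x, n):
        x = min(x, n)
        t = double_arcsine((x, n))
        assert 0.0 <= t <= math.pi
        assert t + double_arcsine((n - x, n)) == pytest.approx(math.pi, abs=1e-12)

    def test_variance(self):
        assert double_arcsine_variance(10) == pytest.approx(1.0 / 10.5)
        with pytest.raises(ValueError):
            double_arcsine_variance(0)

    def test_back_transform_fixed_points(self):
        assert double_arcsine_back(math.pi / 2, 50) == pytest.approx(0.5, abs=1e-9)
        assert double_arcsine_back(0.0, 50) == 0.0
        assert double_arcsine_back(math.pi, 50) == 1.0

    def test_back_transform_rejects_out_of_range(self):
        for t in (-0.1, math.pi + 0.1):
            with pytest.raises(ValueError, match="pi"):
                double_arcsine_back(t, 50)

    def test_round_trip_example(self):
        t = double_arcsine((15, 100))
        assert double_arcsine_back(t, 100) == pytest.approx(0.15, abs=0.01)

    @given(st.integers(20, 2000), st.floats(0.0, 1.0))
    def test_round_trip_within_one_percent(self, n, frac):
        x = int(round(frac * n))
        t = double_arcsine((x, n))
        assert double_arcsine_back(t, n) == pytest.approx(x / n, abs=0.01)


class TestWilson:
    def test_zero_events_lower_bound_is_exactly_zero(self):
        low, high = wilson_ci((0, 10))
        assert low == 0.0
        assert 0.0 < high < 1.0

    def test_all_events_upper_bound_is_exactly_one(self):
        low, high = wilson_ci((10, 10))
        assert high == 1.0

    def test_half_and_half(self):
        low, high = wilson_ci((5, 10))
        assert low == pytest.approx(0.2366, abs=1e-3)
        assert high == pytest.approx(0.7634, abs=1e-3)

    @given(st.integers(0, 100), st.integers(1, 100), st.floats(0.5, 0.999))
    def test_interval_brackets_the_estimate(self, x, n, conf):
        x = min(x, n)
        low, high = wilson_ci((x, n), conf)
        assert 0.0 <= low <= x / n <= high <= 1.0

    def test_exact_coverage_at_small_sample(self):
        """Exact binomial coverage of the 95% Wilson interval at n=50,
        p=0.1 (enumeration over all outcomes): near-nominal, mildly
        conservative at this sample size."""
        n, p = 50, 0.1
        cover = sum(
            stats.binom.pmf(x, n, p)
            for x in range(n + 1)
            if wilson_ci((x, n))[0] <= p <= wilson_ci((x, n))[1]
        )
        assert 0.93 <= cover <= 0.975

    def test_rejects_bad_confidence(self):
        with pytest.raises(ValueError, match="conf"):
            wilson_ci((1, 10), 1.0)


class TestPooling:
    def test_single_study_identity(self):
        est = pool_random_effects([(23, 200)])
        assert est.tau_sq == 0.0
        assert est.pooled_p == pytest.approx(0.115, abs=1e-3)
        assert est.ci_low <= est.pooled_p <= est.ci_high

    def test_identical_studies(self):
        est = pool_random_effects([(10, 100)] * 7)
        assert est.tau_sq == pytest.approx(0.0, abs=1e-12)
        assert est.pooled_p == pytest.approx(0.10, abs=1e-3)

    def test_matches_metafor_reference(self):
        """Frozen values from R metafor (escalc PFT + rma DL +
        transf.ipft.hm) on a five-study set; the transform there is half
        ours, so the location scales by 2 and tau-squared by 4."""
        est = pool_random_effects([(2, 30), (5, 60), (9, 100), (0, 45), (12, 80)])
        assert est.t_pooled / 2 == pytest.approx(0.2827048812, abs=1e-9)
        assert est.tau_sq / 4 == pytest.approx(0.0090329303, abs=1e-9)
        assert est.se_t / 2 == pytest.approx(0.0518463995, abs=1e-9)
        assert est.pooled_p == pytest.approx(0.0700764830, abs=1e-9)
        assert est.ci_low == pytest.approx(0.0242345430, abs=1e-9)
        assert est.ci_high == pytest.approx(0.1338948495, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            pool_random_effects([])

    @given(
        st.lists(
            st.tuples(st.integers(5, 50), st.integers(60, 400)), min_size=2, max_size=8
        )
    )
    def test_homogeneous_pool_within_study_range(self, studies):
        est = pool_random_effects(studies)
        props = [x / n for x, n in studies]
        if est.tau_sq == 0.0:
            assert min(props) - 1e-6 <= est.pooled_p <= max(props) + 1e-6

    def test_study_proportion_invariants(self):
        with pytest.raises(ValueError):
            StudyProportion(5, 0)
        with pytest.raises(ValueError):
            StudyProportion(11, 10)
        with pytest.raises(ValueError):
            StudyProportion(-1, 10)


def test_study_table_io_round_trip(tmp_path):
    path = tmp_path / "studies.csv"
    path.write_text("study_id,events,total\na,2,30\nb,5,60\n")
    studies = read_study_table(path)
    assert studies == [StudyProportion(2, 30), StudyProportion(5, 60)]
    est = pool_random_effects(studies)
    out = tmp_path / "pooled.json"
    write_pooled_estimate(est, out)
    assert "pooled_p" in out.read_text()
    with pytest.raises(ValueError, match="columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("study_id,count\na,2\n")
        read_study_table(bad)
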