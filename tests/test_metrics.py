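"""Validation metrics: bias, accuracy, CIs, and the CI-overlap rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfrbench import (
    PerformanceSummary,
    bias_ci,
    compare_by_ci_overlap,
    iqr_bias,
    median_bias,
    p_accuracy,
    p_accuracy_ci,
    performance_table,
    summarize_performance,
)


class TestMedianBias:
    def test_identity_gives_zero(self):
        x = np.array([50.0, 80.0, 120.0])
        assert median_bias(x, x) == 0.0

    def test_odd_and_even_medians(self):
        mgfr = np.zeros(3)
        assert median_bias(np.array([-2.0, 1.0, 5.0]), mgfr) == 1.0
        assert median_bias(np.array([-2.0, 1.0, 5.0, 9.0]), np.zeros(4)) == 3.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            median_bias([1.0, 2.0], [1.0])

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=30),
        st.lists(st.floats(min_value=10, max_value=150), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_swap(self, a, b):
        n = min(len(a), len(b))
        egfr, mgfr = np.array(a[:n]) + np.array(b[:n]), np.array(b[:n])
        assert median_bias(egfr, mgfr) == pytest.approx(-median_bias(mgfr, egfr), abs=1e-9)


class TestBiasCi:
    def test_degenerate_constant_differences(self):
        mgfr = np.full(20, 100.0)
        lo, hi = bias_ci(mgfr + 4.0, mgfr, seed=1)
        assert (lo, hi) == (4.0, 4.0)

    def test_same_seed_reproduces_interval(self, rng):
        mgfr = rng.uniform(60, 120, 200)
        egfr = mgfr + rng.normal(0, 5, 200)
        assert bias_ci(egfr, mgfr, seed=7) == bias_ci(egfr, mgfr, seed=7)

    def test_interval_width_matches_asymptotic_median_se(self, rng):
        # N(0,1) differences, n=2000: width ~ 2*1.96*1.2533/sqrt(2000) ~ 0.11
        mgfr = np.full(2000, 100.0)
        egfr = mgfr + rng.standard_normal(2000)
        lo, hi = bias_ci(egfr, mgfr, seed=3)
        assert lo < 0.0 < hi or abs(lo) < 0.08  # interval essentially around 0
        assert 0.06 < hi - lo < 0.17

    def test_interval_brackets_point_estimate(self, rng):
        mgfr = rng.uniform(40, 140, 150)
        egfr = mgfr + rng.normal(3, 8, 150)
        lo, hi = bias_ci(egfr, mgfr, seed=11)
        assert lo <= median_bias(egfr, mgfr) <= hi

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            bias_ci([1.0], [1.0], seed=0)


class TestPAccuracy:
    def test_perfect_agreement_is_100(self):
        x = np.linspace(20, 150, 9)
        assert p_accuracy(x, x, 0.30) == 100.0

    def test_boundary_counts_as_within(self):
        mgfr = np.array([100.0, 100.0, 100.0, 100.0])
        egfr = np.array([131.0, 129.0, 70.0, 71.0])
        assert p_accuracy(egfr, mgfr, 0.30) == 75.0

    def test_p20_never_exceeds_p30(self, rng):
        mgfr = rng.uniform(30, 150, 300)
        egfr = mgfr * rng.lognormal(0, 0.25, 300)
        assert p_accuracy(egfr, mgfr, 0.20) <= p_accuracy(egfr, mgfr, 0.30)

    def test_matches_brute_force_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 50))
            mgfr = rng.uniform(10, 150, n)
            egfr = mgfr * rng.lognormal(0, 0.3, n)
            brute = 100 * sum(
                1 for e, m in zip(egfr, mgfr) if abs(e - m) <= 0.30 * m
            ) / n
            assert p_accuracy(egfr, mgfr, 0.30) == pytest.approx(brute, abs=1e-12)


class TestProportionCi:
    def test_reproduces_published_wald_width(self):
        # P30 65.4% at n=1892 prints as (63.3; 67.6) in validation tables
        lo, hi = p_accuracy_ci(65.4, 1892)
        assert lo == pytest.approx(63.3, abs=0.15)
        assert hi == pytest.approx(67.6, abs=0.15)

    def test_half_at_n100(self):
        lo, hi = p_accuracy_ci(50.0, 100)
        assert (round(lo, 1), round(hi, 1)) == (40.2, 59.8)

    def test_degenerate_100_percent_clips(self):
        assert p_accuracy_ci(100.0, 50) == (100.0, 100.0)

    def test_wilson_variant_differs_and_nests_inside_0_100(self):
        lo, hi = p_accuracy_ci(100.0, 50, method="wilson")
        assert 0 < lo < 100.0 and hi == pytest.approx(100.0)


class TestIqrBias:
    def test_constant_differences(self):
        mgfr = np.full(6, 50.0)
        width, q1, q3 = iqr_bias(mgfr + 2.0, mgfr)
        assert (width, q1, q3) == (0.0, 2.0, 2.0)

    def test_linear_interpolation_quantiles(self):
        diffs = np.arange(1.0, 9.0)
        width, q1, q3 = iqr_bias(diffs + 100.0, np.full(8, 100.0))
        assert (q1, q3, width) == (2.75, 6.25, 3.5)

    def test_width_invariant_to_location_shift(self, rng):
        mgfr = rng.uniform(40, 120, 50)
        egfr = mgfr + rng.normal(0, 6, 50)
        w0, *_ = iqr_bias(egfr, mgfr)
        w1, *_ = iqr_bias(egfr + 7.5, mgfr)
        assert w1 == pytest.approx(w0, abs=1e-9)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            iqr_bias([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


def _summary(eq, ci, stratum="all"):
    return PerformanceSummary(
        equation=eq, stratum=stratum, n=100, median_bias=sum(ci) / 2, bias_ci=ci,
        p30=80.0, p30_ci=ci, p20=60.0, p20_ci=ci,
    )


class TestCiOverlapRule:
    def test_published_europe_bias_intervals_are_different(self):
        verdict = compare_by_ci_overlap(
            _summary("EKFC", (1.59, 2.91)), _summary("CKD-EPI", (16.49, 18.47)), "bias"
        )
        assert verdict.different

    def test_published_us_bias_intervals_overlap(self):
        verdict = compare_by_ci_overlap(
            _summary("EKFC", (-1.69, 2.24)), _summary("r-LMR", (-5.08, -1.65)), "bias"
        )
        assert not verdict.different

    def test_touching_endpoints_count_as_overlap(self):
        verdict = compare_by_ci_overlap(_summary("a", (0.0, 1.0)), _summary("b", (1.0, 2.0)), "bias")
        assert not verdict.different

    def test_symmetric_in_arguments(self, rng):
        for _ in range(30):
            ia = tuple(sorted(rng.uniform(-10, 10, 2)))
            ib = tuple(sorted(rng.uniform(-10, 10, 2)))
            va = compare_by_ci_overlap(_summary("a", ia), _summary("b", ib), "bias")
            vb = compare_by_ci_overlap(_summary("b", ib), _summary("a", ia), "bias")
            assert va.different == vb.different

    def test_stratum_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="strat"):
            compare_by_ci_overlap(
                _summary("a", (0, 1), "all"), _summary("b", (2, 3), "males"), "bias"
            )


class TestPerformanceTable:
    def test_perfect_equation_row(self, rng):
        mgfr = rng.uniform(40, 130, 60)
        df = pd.DataFrame({"mgfr_ml_min_173": mgfr, "egfr_EKFC": mgfr})
        table = performance_table(df, ["EKFC"], seed=5)
        row = table.iloc[0]
        assert row["median_bias"] == 0.0 and row["p30"] == 100.0

    def test_schema_covers_all_reported_metrics(self, rng):
        mgfr = rng.uniform(40, 130, 80)
        df = pd.DataFrame(
            {
                "mgfr_ml_min_173": mgfr,
                "egfr_EKFC": mgfr * 1.05,
                "egfr_CKD-EPI": mgfr * 1.25,
                "egfr_r-LMR": mgfr * 0.95,
            }
        )
        table = performance_table(df, ["EKFC", "CKD-EPI", "r-LMR"], seed=5)
        assert len(table) == 3
        for col in (
            "stratum", "equation", "n", "median_bias", "bias_ci_low", "bias_ci_high",
            "iqr_width", "iqr_q1", "iqr_q3", "p30", "p30_ci_low", "p30_ci_high",
            "p20", "p20_ci_low", "p20_ci_high",
        ):
            assert col in table.columns

    def test_empty_stratum_row_has_no_metrics(self, rng):
        mgfr = rng.uniform(40, 130, 30)
        df = pd.DataFrame({"mgfr_ml_min_173": mgfr, "egfr_EKFC": mgfr})
        strata = {"none": np.zeros(30, dtype=bool), "all": np.ones(30, dtype=bool)}
        table = performance_table(df, ["EKFC"], strata, seed=5)
        empty = table[table["stratum"] == "none"].iloc[0]
        assert empty["n"] == 0 and math.isnan(empty["median_bias"])

    def test_overestimating_equation_flagged_worse_on_bias(self, rng):
        mgfr = rng.uniform(60, 120, 400)
        df = pd.DataFrame(
            {"mgfr_ml_min_173": mgfr, "egfr_EKFC": mgfr, "egfr_CKD-EPI": mgfr + 18.0}
        )
        table = performance_table(df, ["EKFC", "CKD-EPI"], seed=5)
        ekfc = table[table["equation"] == "EKFC"].iloc[0]
        assert "CKD-EPI" in ekfc["bias_better_than"]


class TestSummarizeDegenerate:
    def test_small_n_degrades_gracefully(self):
        s = summarize_performance([100.0], [90.0], "EKFC", seed=1)
        assert s.n == 1 and s.median_bias == 10.0
        assert math.isnan(s.bias_ci[0]) and math.isnan(s.bias_iqr_width)
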