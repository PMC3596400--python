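"""Bland-Altman closed forms, accuracy enumeration, staging, paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfrnet.evaluation import (
    accuracy_summary,
    bland_altman,
    compare_models,
    metrics_table,
    staging_concordance,
)


class TestBlandAltman:
    def test_constructed_difference_vector_precision(self):
        """d = [-2,-1,0,1,2] has SD sqrt(2.5), so precision = 3.92*sqrt(2.5)."""
        s = np.array([50.0, 60.0, 70.0, 80.0, 90.0])
        e = s + np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        out = bland_altman(e, s)
        assert out.precision == pytest.approx(3.92 * np.sqrt(2.5), abs=1e-9)

    def test_identical_estimator_degenerate(self):
        s = np.array([30.0, 60.0, 90.0, 120.0])
        out = bland_altman(s, s)
        assert out.precision == 0.0
        assert out.slope == pytest.approx(0.0, abs=1e-12)
        assert out.intercept == pytest.approx(0.0, abs=1e-12)

    def test_precision_equals_392_sd(self, rng):
        s = rng.uniform(20, 120, 500)
        e = s + rng.normal(0, 12, 500)
        out = bland_altman(e, s)
        assert out.precision == pytest.approx(3.92 * out.sd_difference, abs=1e-9)
        assert out.precision >= 0

    def test_gaussian_difference_precision_range(self):
        rng = np.random.default_rng(123)
        s = rng.uniform(40, 100, 10_000)
        e = s + rng.normal(0, 10, 10_000)
        out = bland_altman(e, s)
        assert 38.0 <= out.precision <= 40.4

    def test_acceptability_flag_threshold(self, rng):
        s = rng.uniform(40, 100, 300)
        tight = bland_altman(s + rng.normal(0, 5, 300), s)
        loose = bland_altman(s + rng.normal(0, 25, 300), s)
        assert tight.precision_acceptable
        assert not loose.precision_acceptable

    def test_regression_matches_normal_equations_oracle(self, rng):
        """OLS of d on the average agrees with the closed-form solution."""
        for _ in range(20):
            s = rng.uniform(10, 130, 50)
            e = s * rng.uniform(0.7, 1.3) + rng.normal(0, 8, 50)
            out = bland_altman(e, s)
            d = e - s
            avg = (e + s) / 2
            A = np.column_stack([np.ones(50), avg])
            beta = np.linalg.solve(A.T @ A, A.T @ d)
            assert out.intercept == pytest.approx(beta[0], abs=1e-9)
            assert out.slope == pytest.approx(beta[1], abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestAccuracy:
    def test_hand_enumerated_tolerance_bands(self):
        e = np.array([84.0, 100.0, 116.0, 131.0])
        s = np.full(4, 100.0)
        out = accuracy_summary(e, s)
        assert out.p15 == 25.0
        assert out.p30 == 75.0
        assert out.p50 == 100.0

    def test_median_percent_absolute_difference(self):
        out = accuracy_summary([90.0, 110.0, 95.0], [100.0, 100.0, 100.0])
        assert out.median_pct_absolute_difference == pytest.approx(10.0)

    def test_perfect_estimator(self):
        s = np.array([20.0, 50.0, 80.0])
        out = accuracy_summary(s, s)
        assert (out.p15, out.p30, out.p50) == (100.0, 100.0, 100.0)
        assert out.median_difference == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_tolerance_bands_nested(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(5, 150, 40)
        e = s * rng.lognormal(0, 0.5, 40)
        out = accuracy_summary(e, s)
        assert 0 <= out.p15 <= out.p30 <= out.p50 <= 100

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            accuracy_summary([50.0, 50.0, 50.0], [50.0, 0.0, 50.0])


class TestStaging:
    def test_perfect_agreement_all_zero(self):
        s = np.array([95.0, 70.0, 45.0, 20.0, 10.0])
        out = staging_concordance(s, s)
        assert out.misclassification_rate == 0.0
        assert out.misclassification_below_60 == 0.0
        assert out.misclassification_below_15 == 0.0

    def test_every_record_shifted_one_stage(self):
        s = np.array([95.0, 70.0, 45.0, 20.0])
        e = np.array([70.0, 45.0, 20.0, 10.0])
        out = staging_concordance(e, s)
        assert out.misclassification_rate == 1.0

    def test_hand_enumerated_threshold_swap(self):
        out = staging_concordance(np.array([50.0, 70.0, 45.0]), np.array([70.0, 50.0, 45.0]))
        assert out.misclassification_below_60 == pytest.approx(2 / 3)

    def test_cross_table_row_sums_match_reference_counts(self, rng):
        s = rng.uniform(5, 150, 200)
        e = s * rng.lognormal(0, 0.3, 200)
        out = staging_concordance(e, s)
        from gfrnet.equations import stage_vector

        ref_counts = np.bincount(stage_vector(s), minlength=6)[1:]
        np.testing.assert_array_equal(out.cross_table.sum(axis=1), ref_counts)
        assert out.cross_table.sum() == 200

    def test_per_stage_ratio_conditions_on_estimated_stage(self):
        # 2 records estimated stage 1, one truly stage 1 -> ratio 0.5
        s = np.array([95.0, 70.0, 95.0])
        e = np.array([95.0, 95.0, 95.0])
        out = staging_concordance(e, s)
        assert out.per_stage_correct_ratio[1] == pytest.approx(2 / 3)


class TestCompareModels:
    def test_identical_estimators_degenerate(self, rng):
        s = rng.uniform(20, 120, 50)
        e = s * 1.1
        report = compare_models(e, e, s)
        assert report["wilcoxon"]["skipped"]
        assert report["mcnemar"]["skipped"]
        assert report["regression"]["slope_difference"] == pytest.approx(0.0, abs=1e-9)

    def test_mcnemar_continuity_corrected_statistic(self, rng):
        """Discordant counts b=5, c=15 give chi2 = (|5-15|-1)^2/20 = 4.05."""
        s = np.full(40, 100.0)
        e_a = np.full(40, 100.0)
        e_b = np.full(40, 100.0)
        # 5 records: A within 30%, B outside; 15 records: A outside, B within
        e_a[:5] = 100.0
        e_b[:5] = 200.0
        e_a[5:20] = 200.0
        e_b[5:20] = 100.0
        # remaining 20 concordant hits
        report = compare_models(e_a, e_b, s)
        assert report["mcnemar"]["b"] == 5
        assert report["mcnemar"]["c"] == 15
        assert report["mcnemar"]["statistic"] == pytest.approx(4.05)

    def test_wilcoxon_detects_offset(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(40, 120, 100)
        e_a = s + rng.normal(0, 3, 100)
        e_b = e_a + 10.0  # fixed offset worsens B's errors
        report = compare_models(e_a, e_b, s)
        assert not report["wilcoxon"]["skipped"]
        assert report["wilcoxon"]["p_value"] < 0.05

    def test_slope_difference_recovered(self, rng):
        s = rng.uniform(20, 130, 200)
        e_a = s.copy()
        e_b = s * 1.4  # d_b = 0.4 s, slope vs average differs from A's zero
        report = compare_models(e_a, e_b, s)
        assert report["regression"]["slope_p_value"] < 1e-6


def test_metrics_table_one_row_per_estimator(rng):
    s = rng.uniform(20, 120, 100)
    table = metrics_table({"a": s * 1.1, "b": s * 0.9}, s)
    assert list(table["estimator"]) == ["a", "b"]
    assert {"precision", "p30", "stage_misclassification"} <= set(table.columns)
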