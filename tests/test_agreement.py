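"""Calibration regression, Bland-Altman limits and timing comparison."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import rehabscore as rs
from rehabscore.agreement import (
    AgreementReport,
    bland_altman,
    build_report,
    calibration_regression,
    time_comparison,
)


class TestCalibrationRegression:
    def test_identity_agreement(self):
        x = [1.0, 5.0, 9.0, 14.0]
        r = calibration_regression(x, x)
        assert r["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert r["slope"] == pytest.approx(1.0)
        assert r["r_squared"] == pytest.approx(1.0)

    def test_exact_linearity(self):
        r = calibration_regression([1, 2, 3], [2, 4, 6])
        assert r["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert r["slope"] == pytest.approx(2.0)
        assert r["r_squared"] == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        # Sxy = 2, Sxx = 2 -> slope 1; intercept = 5/3 - 1 = 2/3; R^2 = 0.75
        r = calibration_regression([0, 1, 2], [1, 1, 3])
        assert r["slope"] == pytest.approx(1.0)
        assert r["intercept"] == pytest.approx(2.0 / 3.0)
        assert r["r_squared"] == pytest.approx(0.75)

    def test_slope_ci_brackets_slope(self, rng):
        x = rng.uniform(0, 100, 50)
        y = 2.0 + 0.9 * x + rng.normal(0, 5, 50)
        r = calibration_regression(x, y)
        lo, hi = r["slope_ci_95"]
        assert lo < r["slope"] < hi

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_regression([3, 3, 3], [1, 2, 3])

    @given(x=arrays(float, 8, elements=st.floats(-50, 50), unique=True))
    def test_self_regression_is_identity(self, x):
        r = calibration_regression(x, x)
        assert r["slope"] == pytest.approx(1.0, abs=1e-6)
        assert r["intercept"] == pytest.approx(0.0, abs=1e-5)
        assert r["r_squared"] == pytest.approx(1.0, abs=1e-9)


class TestBlandAltman:
    def test_perfect_agreement(self):
        x = [10.0, 20.0, 30.0]
        block = bland_altman(x, x)["deviation"]
        assert block["mean"] == 0.0
        assert block["sd"] == 0.0
        assert block["within_limit_percent"] == 100.0

    def test_hand_computed_example(self):
        block = bland_altman([10, 20, 30], [12, 18, 30])["deviation"]
        assert block["mean"] == pytest.approx(0.0)
        assert block["sd"] == pytest.approx(2.0)
        np.testing.assert_allclose(block["limits"], [-3.92, 3.92])
        assert block["within_limit_percent"] == 100.0

    def test_gaussian_within_limit_fraction(self, rng):
        """~95% of Gaussian deviations fall inside mean +/- 1.96 SD."""
        n = 100_000
        physician = np.full(n, 50.0)
        system = physician - rng.normal(0.0, 3.0, n)
        block = bland_altman(physician, system)["deviation"]
        assert block["within_limit_percent"] == pytest.approx(95.0, abs=0.5)

    def test_zero_physician_excluded_from_relative_stats(self):
        result = bland_altman([0.0, 10.0, 20.0, 40.0], [1.0, 12.0, 18.0, 40.0])
        rel = result["relative_deviation"]
        assert rel["available"] is True
        assert rel["excluded_zero_count"] == 1
        assert rel["n"] == 3
        # -20%, +10%, 0%
        assert rel["mean"] == pytest.approx(-10.0 / 3.0)

    def test_all_zero_physician_marks_relative_unavailable(self):
        result = bland_altman([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert result["relative_deviation"]["available"] is False

    def test_counts_conserve_n(self, rng):
        p = rng.uniform(0, 100, 50)
        s = p + rng.normal(0, 4, 50)
        block = bland_altman(p, s)["deviation"]
        assert block["within_limit_count"] + block["outside_limit_count"] == 50

    @given(
        p=arrays(float, 10, elements=st.floats(1, 100)),
        s=arrays(float, 10, elements=st.floats(1, 100)),
        shift=st.floats(-50, 50),
    )
    def test_mean_linearity_and_shift_invariance(self, p, s, shift):
        block = bland_altman(p, s)["deviation"]
        assert block["mean"] == pytest.approx(p.mean() - s.mean(), abs=1e-9)
        shifted = bland_altman(p + shift, s + shift)["deviation"]
        assert (
            shifted["within_limit_percent"] == block["within_limit_percent"]
        )


class TestTimeComparison:
    def test_identical_groups_give_t_zero(self):
        r = time_comparison([1, 2, 3], [1, 2, 3], preparation_min=0.0)
        assert r["t_statistic"] == pytest.approx(0.0)
        assert r["p_value"] == pytest.approx(1.0)
        assert not r["significant"]

    def test_hand_computed_pooled_t(self):
        # pooled sd = 1, se = sqrt(2/3), t = -3/se
        r = time_comparison([1, 2, 3], [4, 5, 6], preparation_min=0.0)
        assert r["t_statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert r["p_value"] == pytest.approx(0.0214, abs=2e-3)

    def test_preparation_offset_shifts_system_mean(self):
        r = time_comparison([10.0, 12.0], [20.0, 22.0], preparation_min=1.0)
        assert r["system_mean"] == pytest.approx(12.0)

    def test_power_at_study_scale(self):
        """Simulated study-scale groups separate in >= 99 of 100 runs."""
        from rehabscore.synthcohort import (
            PHYSICIAN_TIME_MEAN,
            PHYSICIAN_TIME_SD,
            SYSTEM_TIME_MEAN,
            SYSTEM_TIME_SD,
        )

        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sys_t = np.maximum(3.0, rng.normal(SYSTEM_TIME_MEAN, SYSTEM_TIME_SD, 120))
            phy_t = np.maximum(
                3.0, rng.normal(PHYSICIAN_TIME_MEAN, PHYSICIAN_TIME_SD, 120)
            )
            if time_comparison(sys_t, phy_t, preparation_min=0.0)["p_value"] < 0.05:
                hits += 1
        assert hits >= 99

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            time_comparison([5.0], [1.0, 2.0])

    def test_paired_variant_needs_equal_sizes(self):
        with pytest.raises(ValueError, match="paired"):
            time_comparison([1, 2, 3], [1, 2], paired=True)


def _predicted_records(rng, n=30):
    records = []
    for k in range(n):
        upper = float(rng.uniform(0, 66))
        lower = float(rng.uniform(0, 34))
        records.append(
            rs.AssessmentRecord(
                subject_id=f"S{k}",
                movement_scores=np.empty(0),
                physician_upper=upper,
                physician_lower=lower,
                physician_total=upper + lower,
                system_upper=upper + float(rng.normal(0, 2)),
                system_lower=lower + float(rng.normal(0, 2)),
                system_total=upper + lower + float(rng.normal(0, 3)),
            )
        )
    return records


class TestBuildReport:
    def test_report_complete_and_counts_conserve(self, rng):
        records = _predicted_records(rng)
        report = build_report(
            records,
            system_times=rng.uniform(5, 20, 30),
            physician_times=rng.uniform(10, 35, 30),
        )
        assert report.n == 30
        for target in ("total", "upper", "lower"):
            assert "slope" in report.regression[target]
            dev = report.deviations[target]["deviation"]
            assert dev["within_limit_count"] + dev["outside_limit_count"] == 30
        assert report.timing is not None

    def test_json_round_trip(self, rng, tmp_path):
        records = _predicted_records(rng)
        report = build_report(records)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = AgreementReport.from_json(path)
        assert loaded.to_dict() == report.to_dict()

    def test_markdown_summary_mentions_all_targets(self, rng):
        text = build_report(_predicted_records(rng)).to_markdown()
        for label in ("Total score", "Upper score", "Lower score"):
            assert label in text

    def test_missing_predictions_rejected(self, rng):
        records = _predicted_records(rng)
        records[3] = dataclasses.replace(records[3], system_total=None)
        with pytest.raises(ValueError, match="system total"):
            build_report(records)
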