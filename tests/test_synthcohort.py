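"""Synthetic templates, severity degradation, FMA labels and cohorts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rehabscore as rs
from rehabscore.synthcohort import (
    N_LOWER_ITEMS,
    N_UPPER_ITEMS,
    PHYSICIAN_TIME_MEAN,
)


class TestGenerateTemplate:
    def test_deterministic_given_id_and_seed(self):
        a = rs.generate_template("u04_elbow_flexion", seed=9)
        b = rs.generate_template("u04_elbow_flexion", seed=9)
        for name in a.channels:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])

    def test_different_seeds_differ(self):
        a = rs.generate_template("u04_elbow_flexion", seed=9)
        b = rs.generate_template("u04_elbow_flexion", seed=10)
        assert not np.array_equal(a.channels["angle_deg"], b.channels["angle_deg"])

    def test_cyclic_angle_profile_closes(self, template_recording):
        angle = template_recording.channels["angle_deg"]
        assert angle[0] == pytest.approx(angle[-1], abs=1e-9)

    def test_velocity_channel_consistent_with_angle_derivative(
        self, template_recording
    ):
        rate = template_recording.sampling_rate
        angle = template_recording.channels["angle_deg"]
        vel = template_recording.channels["angular_velocity_dps"]
        fd = np.gradient(angle) * rate
        # central differences of a smooth profile: O(dt^2 * max|angular accel|)
        omega = 2 * np.pi / template_recording.duration
        max_accel = np.max(np.abs(vel)) * omega
        tol = 2 * max_accel / rate
        assert np.max(np.abs(fd[1:-1] - vel[1:-1])) < tol

    def test_hand_task_has_flex_channels(self):
        rec = rs.generate_template(
            "u16_finger_mass_flexion",
            seed=1,
            channels=(
                "angle_deg",
                "angular_velocity_dps",
                "acceleration_mps2",
                "flex_1",
                "flex_2",
                "flex_3",
                "flex_4",
                "flex_5",
            ),
        )
        flex = [c for c in rec.channel_names if c.startswith("flex_")]
        assert len(flex) == 5
        for name in flex:
            values = rec.channels[name]
            assert values.min() >= 0.0 and values.max() <= 1.0

    @pytest.mark.parametrize("duration, rate", [(0.0, 30.0), (4.0, 0.0), (-1.0, 30.0)])
    def test_nonpositive_duration_or_rate_rejected(self, duration, rate):
        with pytest.raises(ValueError):
            rs.generate_template("m", duration=duration, sampling_rate=rate)


class TestDegradeMotion:
    def test_zero_severity_zero_noise_is_identity(self, template_recording):
        profile = rs.SeverityProfile.from_severity(0.0, noise_sd=0.0)
        out = rs.degrade_motion(template_recording, profile, seed=3)
        for name in template_recording.channels:
            np.testing.assert_array_equal(
                out.channels[name], template_recording.channels[name]
            )

    def test_full_attenuation_flattens_angle(self, template_recording):
        profile = rs.SeverityProfile(
            severity=1.0, amplitude_attenuation=1.0, speed_factor=1.0,
            tremor_amplitude=0.0, noise_sd=0.0,
        )
        out = rs.degrade_motion(template_recording, profile, seed=3)
        angle = out.channels["angle_deg"]
        np.testing.assert_allclose(angle, angle[0])

    def test_mean_amplitude_attenuation_over_seeds(self, template_recording):
        """At severity 0.5 and attenuation 0.8 the expected angle
        peak-to-peak is 0.6x the template's."""
        template_ptp = np.ptp(template_recording.channels["angle_deg"])
        profile = rs.SeverityProfile(
            severity=0.5, amplitude_attenuation=0.8, speed_factor=1.5,
            tremor_amplitude=0.0, noise_sd=0.3,
        )
        ptps = [
            np.ptp(
                rs.degrade_motion(template_recording, profile, seed=s).channels[
                    "angle_deg"
                ]
            )
            for s in range(50)
        ]
        assert np.mean(ptps) == pytest.approx(0.6 * template_ptp, rel=0.05)

    def test_time_dilation_lengthens_recording(self, template_recording):
        profile = rs.SeverityProfile(
            severity=0.5, speed_factor=2.0, noise_sd=0.0
        )
        out = rs.degrade_motion(template_recording, profile, seed=3)
        assert out.n_samples == 2 * (template_recording.n_samples - 1) + 1
        assert out.sampling_rate == template_recording.sampling_rate

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            rs.SeverityProfile(severity=1.5)
        with pytest.raises(ValueError):
            rs.SeverityProfile(severity=0.5, speed_factor=0.5)
        with pytest.raises(ValueError):
            rs.SeverityProfile(severity=0.5, noise_sd=-1.0)


class TestSimulatePhysicianFma:
    def test_healthy_limit(self):
        upper, lower = rs.simulate_physician_fma(0.0, 0.0, seed=1)
        assert (upper == 2).all() and (lower == 2).all()
        assert upper.sum() + lower.sum() == 100

    def test_no_movement_limit(self):
        upper, lower = rs.simulate_physician_fma(1.0, 0.0, seed=1)
        assert upper.sum() + lower.sum() == 0

    def test_mid_severity_lands_in_middle_band(self):
        # latent 0.5 falls in [1/3, 2/3): every item is 1
        upper, lower = rs.simulate_physician_fma(0.5, 0.0, seed=1)
        assert (upper == 1).all() and (lower == 1).all()
        assert upper.sum() + lower.sum() == 50

    def test_item_counts(self):
        upper, lower = rs.simulate_physician_fma(0.3, 0.2, seed=2)
        assert upper.size == N_UPPER_ITEMS and lower.size == N_LOWER_ITEMS

    @given(severity=st.floats(0, 1), seed=st.integers(0, 2**20))
    def test_items_always_ordinal(self, severity, seed):
        upper, lower = rs.simulate_physician_fma(severity, 0.3, seed=seed)
        assert np.isin(np.concatenate([upper, lower]), (0, 1, 2)).all()

    def test_severity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            rs.simulate_physician_fma(1.2, 0.0, seed=1)

    def test_total_monotone_in_severity_without_rater_noise(self):
        totals = []
        for severity in np.linspace(0, 1, 11):
            upper, lower = rs.simulate_physician_fma(float(severity), 0.0, seed=1)
            totals.append(upper.sum() + lower.sum())
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestGenerateCohort:
    def test_counts_and_totals(self, battery):
        samples = rs.generate_cohort(1, seed=3, config=battery)
        assert len(samples) == 1
        sample = samples[0]
        assert set(sample.recordings) == set(battery.movement_ids)
        assert sample.total == sample.upper_total + sample.lower_total
        assert 0 <= sample.upper_total <= 66
        assert 0 <= sample.lower_total <= 34

    def test_reproducible_from_seed(self, battery):
        small = rs.BatteryConfig(movements=battery.movements[:3])
        a = rs.generate_cohort(4, seed=8, config=small)
        b = rs.generate_cohort(4, seed=8, config=small)
        assert [s.total for s in a] == [s.total for s in b]
        for sa, sb in zip(a, b):
            for mid in sa.recordings:
                np.testing.assert_array_equal(
                    sa.recordings[mid].channels["angle_deg"],
                    sb.recordings[mid].channels["angle_deg"],
                )

    def test_physician_time_mean_matches_generator(self, cohort120):
        mean = np.mean([s.physician_time for s in cohort120])
        assert mean == pytest.approx(PHYSICIAN_TIME_MEAN, abs=1.5)

    def test_times_positive(self, cohort120):
        assert all(s.physician_time > 0 and s.system_time > 0 for s in cohort120)

    def test_recordings_uniform_and_equal_length(self, cohort120):
        sample = cohort120[0]
        for rec in sample.recordings.values():
            lengths = {v.size for v in rec.channels.values()}
            assert len(lengths) == 1
            assert rec.sampling_rate == 30.0

    def test_empty_inputs_rejected(self, battery):
        with pytest.raises(ValueError):
            rs.generate_cohort(0, seed=1, config=battery)
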