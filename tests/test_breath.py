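"""Filtering, breath segmentation, cycle averaging, in vivo axes, regression."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribkin import breath, rotations as rot


class TestLowpassFilter:
    def test_constant_unchanged(self):
        x = np.full(500, 7.3)
        assert np.allclose(breath.lowpass_filter(x, 1.0, 100.0), 7.3, atol=1e-9)

    def test_breathing_band_passes(self):
        t = np.arange(0, 60, 0.01)
        x = np.sin(2 * np.pi * 0.1 * t)
        y = breath.lowpass_filter(x, 1.0, 100.0)
        mid = slice(1000, -1000)
        assert np.ptp(y[mid]) / np.ptp(x[mid]) > 0.99

    def test_noise_band_rejected(self):
        t = np.arange(0, 60, 0.01)
        x = np.sin(2 * np.pi * 5.0 * t)
        y = breath.lowpass_filter(x, 1.0, 100.0)
        assert np.ptp(y[1000:-1000]) / np.ptp(x) < 0.10

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            breath.lowpass_filter(np.zeros(10), 1.0, 100.0)

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            breath.lowpass_filter(np.zeros(500), 60.0, 100.0)


class TestSegmentBreaths:
    def test_pure_sinusoid_yields_five_cycles(self):
        t = np.arange(0, 60, 1 / 60)
        cycles = breath.segment_breaths(np.sin(2 * np.pi * 0.1 * t), 60.0)
        assert len(cycles) == 5

    def test_flat_signal_yields_nothing(self):
        with pytest.warns(UserWarning, match="flat"):
            assert breath.segment_breaths(np.zeros(1000), 100.0) == []

    def test_generator_boundaries_recovered(self, noiseless_sim):
        from ribkin.pipeline import _expansion_signal

        score = _expansion_signal(
            [noiseless_sim.true_joint_angles[f"cv_{i + 1}"] for i in range(8)]
        )
        score = breath.lowpass_filter(score, 1.5, 100.0)
        cycles = breath.segment_breaths(score, 100.0)
        found = np.array([c[0] for c in cycles] + [cycles[-1][1]])
        truth = noiseless_sim.breath_bounds
        assert len(found) == len(truth)
        assert np.abs(found - truth).max() <= 2


class TestResampleCycle:
    def test_linear_ramp(self):
        c = breath.resample_cycle(np.column_stack([np.linspace(0, 10, 200)] * 3))
        assert c.angles_deg.shape == (100, 3)
        assert np.abs(c.angles_deg.mean(axis=0)).max() < 1e-9
        assert np.ptp(c.angles_deg[:, 0]) == pytest.approx(10.0, abs=1e-9)
        steps = np.diff(c.angles_deg[:, 0])
        assert np.allclose(steps, steps[0], atol=1e-9)
        assert np.allclose(c.mean_deg, 5.0, atol=1e-9)

    def test_phase_locked_cycles_agree_across_durations(self):
        wave = lambda phase: np.column_stack(
            [np.sin(2 * np.pi * phase), np.cos(4 * np.pi * phase), phase**2]
        )
        a = breath.resample_cycle(10 * wave(np.linspace(0, 1, 600)))
        b = breath.resample_cycle(10 * wave(np.linspace(0, 1, 1130)))
        assert np.abs(a.angles_deg - b.angles_deg).max() < 0.1

    def test_idempotent_on_resampled_cycle(self):
        c = breath.resample_cycle(np.column_stack([np.sin(np.linspace(0, 6, 300))] * 3))
        again = breath.resample_cycle(c.angles_deg)
        assert np.abs(again.angles_deg - c.angles_deg).max() < 1e-9

    def test_constant_cycle_is_all_zero(self):
        c = breath.resample_cycle(np.full((50, 3), 4.2))
        assert np.abs(c.angles_deg).max() < 1e-12

    def test_short_cycle_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            breath.resample_cycle(np.zeros((5, 3)))


class TestAverageCycles:
    def _cycle(self, arr, jid="j"):
        return breath.resample_cycle(arr, joint_id=jid)

    def test_single_cycle(self):
        c = self._cycle(np.column_stack([np.sin(np.linspace(0, 6, 200))] * 3))
        avg = breath.average_cycles([c])
        assert np.array_equal(avg.mean_deg, c.angles_deg)
        assert np.all(avg.sd_deg == 0) and avg.n_breaths == 1

    def test_mirrored_cycles_cancel(self):
        base = np.column_stack([np.sin(np.linspace(0, 2 * np.pi, 100))] * 3)
        a = breath.BreathCycle("j", 0, 99, base, np.zeros(3))
        b = breath.BreathCycle("j", 0, 99, -base, np.zeros(3))
        avg = breath.average_cycles([a, b])
        assert np.abs(avg.mean_deg).max() < 1e-12

    def test_noisy_replicates_recover_waveform(self, rng):
        truth = 8 * np.column_stack(
            [np.sin(2 * np.pi * np.linspace(0, 1, 100)) for _ in range(3)]
        )
        cycles = [
            breath.BreathCycle("j", 0, 99, truth + rng.normal(0, 0.5, truth.shape), np.zeros(3))
            for _ in range(5)
        ]
        avg = breath.average_cycles(cycles)
        # the mean of 5 replicates with known sigma = 0.5 has s.e. 0.5/sqrt(5);
        # ~95% of points should land within 2 s.e. of the generating waveform
        bound = 2 * 0.5 / np.sqrt(5)
        assert np.mean(np.abs(avg.mean_deg - truth) <= bound) > 0.9
        assert np.abs(avg.sd_deg.mean() - 0.5) < 0.1

    def test_mixed_joints_rejected(self):
        a = self._cycle(np.zeros((100, 3)) + np.linspace(0, 1, 100)[:, None], "j1")
        b = self._cycle(np.zeros((100, 3)) + np.linspace(0, 1, 100)[:, None], "j2")
        with pytest.raises(ValueError, match="different joints"):
            breath.average_cycles([a, b])


def _avg_from_traces(angles, jid="j"):
    c = breath.resample_cycle(angles, joint_id=jid)
    return breath.average_cycles([c])


class TestTotalRotationAxis:
    def test_pure_bucket_oscillation(self):
        phase = np.linspace(0, 1, 400)
        z = 20 * (np.cos(2 * np.pi * phase) - 1) / 2
        avg = _avg_from_traces(np.column_stack([z, 0 * z, 0 * z]))
        ax = breath.total_rotation_axis(avg)
        assert np.allclose(np.abs(ax.axis_angle.axis), [0, 0, 1], atol=1e-9)
        # theta reaches the 20 deg prescription up to phase-grid discretization
        assert ax.axis_angle.theta_deg == pytest.approx(20.0, abs=0.02)
        assert np.allclose(ax.plane_angles_deg, [0, 0, 90], atol=1e-6)

    def test_hinge_axis_recovered(self):
        u = np.array([0.5, 0.5, 0.7071])
        u /= np.linalg.norm(u)
        phase = np.linspace(0, 1, 500)
        theta = 18 * (np.cos(2 * np.pi * phase) - 1) / 2
        angles = np.array(
            [rot.matrix_to_euler(rot.axis_angle_to_matrix(u, th)).as_array() for th in theta]
        )
        ax = breath.total_rotation_axis(_avg_from_traces(angles), reference_axis=u)
        assert rot.angle_between_deg(ax.axis_angle.axis, u) < 0.5

    def test_equal_component_amplitudes_match_composition_oracle(self):
        # equal 10 deg amplitudes on all three Euler components: the expected
        # axis comes from brute-force composition of the two peak rotations
        phase = np.linspace(0, 1, 500)
        w = (np.cos(2 * np.pi * phase) - 1) / 2
        angles = 10 * np.column_stack([w, w, w])
        ax = breath.total_rotation_axis(_avg_from_traces(angles))
        expected = rot.matrix_to_axis_angle(
            Rotation.from_euler("ZYX", [-10, -10, -10], degrees=True).as_matrix()
        )
        assert rot.angle_between_deg(ax.axis_angle.axis, expected.axis) < 0.05
        assert ax.axis_angle.theta_deg == pytest.approx(expected.theta_deg, abs=0.05)
        # composition suppresses the middle (y) component slightly, so the
        # plane angles are only approximately equal (37.5/30.7/37.5 deg)
        assert np.ptp(ax.plane_angles_deg) < 8.0

    def test_degenerate_rotation_flagged(self):
        phase = np.linspace(0, 1, 400)
        tiny = 0.2 * np.column_stack([(np.cos(2 * np.pi * phase) - 1) / 2] * 3)
        with pytest.warns(UserWarning, match="unreliable"):
            ax = breath.total_rotation_axis(_avg_from_traces(tiny))
        assert ax.degenerate


class TestRegression:
    def test_identity(self):
        x = np.linspace(10, 60, 8)
        P = np.column_stack([x, x + 5, 70 - x])
        df = breath.regress_predicted_vs_measured(P, P)
        assert np.allclose(df.slope, 1.0, atol=1e-12)
        assert np.allclose(df.intercept, 0.0, atol=1e-9)
        assert np.allclose(df.r_squared, 1.0)

    def test_matches_closed_form_ols(self, rng):
        x = np.linspace(5, 70, 12)
        y = 0.8 * x + 10 + rng.normal(0, 2, 12)
        P = np.column_stack([x] * 3)
        M = np.column_stack([y] * 3)
        df = breath.regress_predicted_vs_measured(P, M)
        slope_ref, intercept_ref = np.polyfit(x, y, 1)
        assert df.slope[0] == pytest.approx(slope_ref, abs=1e-9)
        assert df.intercept[0] == pytest.approx(intercept_ref, abs=1e-9)
        # 95% CI of the fit should cover the generating parameters
        se = 2 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(df.slope[0] - 0.8) < 3 * se

    def test_constant_predictor_rejected(self):
        P = np.full((5, 3), 30.0)
        M = np.random.default_rng(0).normal(30, 1, (5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            breath.regress_predicted_vs_measured(P, M)

    def test_too_few_pairs_rejected(self):
        P = np.zeros((2, 3))
        with pytest.raises(ValueError):
            breath.regress_predicted_vs_measured(P, P)
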