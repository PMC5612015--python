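"""Pose estimation, tracking precision and the intermarker rigidity screen."""

import numpy as np
import pytest

from ribkin import rotations as rot
from ribkin.rigid_body import (
    MarkerSet,
    TrajectorySet,
    classify_rigidity,
    filter_pose_series,
    fit_pose_series,
    intermarker_distance,
    kabsch,
    tracking_precision,
)


def tetrahedron(span_mm: float) -> np.ndarray:
    """Four markers whose largest pairwise distance is ``span_mm``."""
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return v * (span_mm / (2 * np.sqrt(2)))


def _apply(R, t, pts):
    return pts @ R.T + t


def _orientation_error_deg(Ra, Rb):
    return rot.matrix_to_axis_angle(Ra.T @ Rb, degenerate_tol_deg=0.0).theta_deg


class TestKabsch:
    def test_identity_on_equal_points(self):
        pts = tetrahedron(15)
        R, t, rms = kabsch(pts, pts)
        assert np.abs(R - np.eye(3)).max() < 1e-12
        assert np.linalg.norm(t) < 1e-12 and rms < 1e-12

    def test_recovers_known_transform_exactly(self):
        pts = tetrahedron(15)
        R_true = rot.euler_to_matrix((25, 0, 0))
        t_true = np.array([1.0, 2.0, 3.0])
        R, t, rms = kabsch(pts, _apply(R_true, t_true, pts))
        assert np.abs(R - R_true).max() < 1e-9
        assert np.abs(t - t_true).max() < 1e-9
        assert rms < 1e-9

    def test_reflection_guard(self):
        # mirror-image observations must still yield a proper rotation
        pts = tetrahedron(15)
        obs = pts * np.array([1, 1, -1.0])
        R, _, _ = kabsch(pts, obs)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_reference_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)

    def test_orientation_error_under_noise(self, rng):
        # sigma = 0.12 mm on 4 markers spanning 15 mm: < 1.5 deg in >= 95%
        pts = tetrahedron(15)
        R_true = rot.euler_to_matrix((10, -20, 5))
        moved = _apply(R_true, np.array([4.0, 5, 6]), pts)
        ok = 0
        n = 500
        for _ in range(n):
            R, _, _ = kabsch(pts, moved + rng.normal(0, 0.12, pts.shape))
            ok += _orientation_error_deg(R, R_true) < 1.5
        assert ok / n >= 0.95

    def test_error_decreases_with_markers_and_span(self, rng):
        def mean_err(n_markers, span):
            g = np.random.default_rng(99)
            pts = g.uniform(-span / 2, span / 2, (n_markers, 3))
            errs = []
            for _ in range(150):
                R, _, _ = kabsch(pts, pts + g.normal(0, 0.12, pts.shape))
                errs.append(_orientation_error_deg(R, np.eye(3)))
            return np.mean(errs)

        base = mean_err(4, 15)
        assert mean_err(8, 15) < base
        assert mean_err(4, 30) < base


class TestFitPoseSeries:
    def _markerset(self, span=15):
        pts = tetrahedron(span)
        return MarkerSet("bone", {f"m{i}": pts[i] for i in range(4)})

    def test_static_gives_identity(self):
        ms = self._markerset()
        traj = TrajectorySet(100.0, {m: np.tile(p, (10, 1)) for m, p in ms.markers.items()})
        ps = fit_pose_series(ms, traj)
        assert np.abs(ps.rotations - np.eye(3)).max() < 1e-12
        assert np.abs(ps.translations).max() < 1e-12
        assert ps.rms_residual.max() < 1e-12

    def test_frames_with_too_few_markers_are_missing(self):
        ms = self._markerset()
        pos = {m: np.tile(p, (5, 1)) for m, p in ms.markers.items()}
        for m in ["m0", "m1"]:
            pos[m][2] = np.nan
        ps = fit_pose_series(ms, TrajectorySet(100.0, pos))
        assert not ps.valid[2]
        assert ps.valid[[0, 1, 3, 4]].all()

    def test_all_frames_unfittable_names_body(self):
        ms = self._markerset()
        pos = {m: np.full((4, 3), np.nan) for m in ms.markers}
        with pytest.raises(ValueError, match="bone"):
            fit_pose_series(ms, TrajectorySet(100.0, pos))

    def test_requires_three_noncollinear_markers(self):
        with pytest.raises(ValueError, match="collinear"):
            MarkerSet("bad", {"a": [0, 0, 0], "b": [1, 0, 0], "c": [2, 0, 0]})


class TestFilterPoseSeries:
    def test_preserves_smooth_motion(self, noiseless_sim):
        ps = noiseless_sim.true_poses["vrib_4"]
        f = filter_pose_series(ps, 1.5, 4)
        mid = slice(300, -300)
        errs = [
            _orientation_error_deg(a, b)
            for a, b in zip(f.rotations[mid][::50], ps.rotations[mid][::50])
        ]
        assert max(errs) < 0.05
        assert np.abs(f.translations[mid] - ps.translations[mid]).max() < 0.01

    def test_reduces_noise(self, default_model, noisy_sim):
        raw = fit_pose_series(default_model.bodies["vrib_4"], noisy_sim.trajectories)
        filt = filter_pose_series(raw, 1.5, 4)
        truth = noisy_sim.true_poses["vrib_4"].rotations
        mid = slice(300, -300, 25)
        e_raw = np.mean([_orientation_error_deg(a, b) for a, b in zip(raw.rotations[mid], truth[mid])])
        e_filt = np.mean([_orientation_error_deg(a, b) for a, b in zip(filt.rotations[mid], truth[mid])])
        assert e_filt < 0.4 * e_raw


class TestIntermarkerDistance:
    def test_static_pair_constant(self):
        pos = {
            "a": np.tile([0.0, 0, 0], (400, 1)),
            "b": np.tile([10.0, 0, 0], (400, 1)),
        }
        d = intermarker_distance(TrajectorySet(100.0, pos), "a", "b")
        assert np.allclose(d, 10.0, atol=1e-9)

    def test_articulating_pair_fluctuates_at_driving_frequency(self):
        t = np.arange(0, 40, 0.01)
        # breathing-style sweep from 0 to -15 deg (one-sided, like a real
        # joint excursion, so the distance fundamental is the driving rate)
        theta = np.radians(15) * (np.cos(2 * np.pi * 0.1 * t) - 1) / 2
        b = np.column_stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros_like(t)])
        pos = {"a": np.tile([-10.0, 0, 0], (len(t), 1)), "b": b}
        d = intermarker_distance(TrajectorySet(100.0, pos), "a", "b")
        spec = np.abs(np.fft.rfft(d - d.mean()))
        freqs = np.fft.rfftfreq(len(d), 0.01)
        assert freqs[np.argmax(spec)] == pytest.approx(0.1, abs=0.02)

    def test_filtered_noise_below_sigma(self, rng):
        sigma = 0.12
        pos = {
            "a": np.tile([0.0, 0, 0], (3000, 1)) + rng.normal(0, sigma, (3000, 3)),
            "b": np.tile([10.0, 0, 0], (3000, 1)) + rng.normal(0, sigma, (3000, 3)),
        }
        d = intermarker_distance(TrajectorySet(100.0, pos), "a", "b", filter_cutoff_hz=1.5)
        assert np.std(d) < sigma

    def test_disjoint_tracking_rejected(self):
        pos = {"a": np.full((10, 3), np.nan), "b": np.zeros((10, 3))}
        pos["a"][:5] = 0.0
        pos["b"][:5] = np.nan
        with pytest.raises(ValueError, match="no tracked frames"):
            intermarker_distance(TrajectorySet(100.0, pos), "a", "b")


class TestTrackingPrecision:
    def test_noiseless_is_zero(self):
        pos = {"a": np.tile([0.0, 0, 0], (50, 1)), "b": np.tile([8.0, 0, 0], (50, 1))}
        mean, sem, n = tracking_precision(TrajectorySet(100.0, pos), [("a", "b")])
        assert mean == 0.0 and n == 1

    def test_matches_analytic_distance_noise(self, rng):
        # two markers with isotropic sigma noise: SD(distance) -> sigma*sqrt(2)
        sigma = 0.12
        T, npairs = 400, 200
        pos = {}
        pairs = []
        for i in range(npairs):
            base = rng.uniform(-50, 50, 3)
            pos[f"p{i}a"] = np.tile(base, (T, 1)) + rng.normal(0, sigma, (T, 3))
            pos[f"p{i}b"] = np.tile(base + [12.0, 0, 0], (T, 1)) + rng.normal(0, sigma, (T, 3))
            pairs.append((f"p{i}a", f"p{i}b"))
        mean, sem, n = tracking_precision(TrajectorySet(100.0, pos), pairs)
        assert n == npairs
        assert abs(mean - sigma * np.sqrt(2)) / (sigma * np.sqrt(2)) < 0.15

    def test_needs_at_least_one_pair(self):
        with pytest.raises(ValueError):
            tracking_precision(TrajectorySet(100.0, {"a": np.zeros((5, 3))}), [])


class TestRigidityScreen:
    def test_co_osseous_noise_only_is_rigid(self, rng):
        sigma = 0.12
        pos = {
            "a": np.tile([0.0, 0, 0], (3000, 1)) + rng.normal(0, sigma, (3000, 3)),
            "b": np.tile([9.0, 0, 0], (3000, 1)) + rng.normal(0, sigma, (3000, 3)),
        }
        r = classify_rigidity(
            TrajectorySet(100.0, pos), "a", "b", "co-osseous", precision_mm=sigma * np.sqrt(2)
        )
        assert r.verdict == "same-rigid-body"

    def test_cross_joint_pair_is_mobile(self, default_model, noisy_sim):
        # a marker pair spanning a scripted 15+ deg costovertebral joint
        pair = default_model.crossjoint_pairs()[default_model.joints.index(default_model.joint("cv_4"))]
        r = classify_rigidity(noisy_sim.trajectories, *pair, "cross-body", precision_mm=0.17)
        assert r.verdict == "mobile-joint"

    def test_synthetic_bending_is_flagged(self, default_model):
        from ribkin import synthetic as syn

        flex_marker = default_model.bodies["srib_4"].marker_ids[1]
        script = syn.default_motion_script(
            default_model, seed=4, n_breaths=3, marker_flex_mm={flex_marker: 2.0}
        )
        sim = syn.simulate_breathing(default_model, script)
        other = default_model.bodies["srib_4"].marker_ids[0]
        r = classify_rigidity(sim.trajectories, other, flex_marker, "co-osseous", precision_mm=0.17)
        assert r.verdict == "bending-suspected"
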