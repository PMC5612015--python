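"""Per-frame rigid-body pose estimation and the intermarker-distance screen.

Each bone (or declared group of two-to-three vertebrae) carries >= 3
implanted radio-opaque markers whose positions are known in the bone's
CT/model frame. Given the per-frame reconstructed 3D marker positions, the
pose of the bone in each frame is the least-squares orthogonal Procrustes
(Kabsch) fit, with a reflection guard forcing det = +1.

Intermarker distances decide the rigid-body model: constant distance between
two markers means they can share a rigid body; fluctuation in a co-osseous
pair suggests the bone bends; fluctuation across a joint means the two
segments must be modelled as separate rigid bodies. Tracking precision is
the standard deviation of co-osseous intermarker distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotations import RigidTransform

__all__ = [
    "MarkerSet",
    "TrajectorySet",
    "PoseSeries",
    "RigidityReport",
    "kabsch",
    "fit_pose_series",
    "filter_pose_series",
    "intermarker_distance",
    "tracking_precision",
    "classify_rigidity",
]

#: smallest singular value (mm) of centered marker positions below which the
#: marker cloud is considered collinear and cannot constrain a pose
COLLINEAR_TOL = 1e-6


def _collinear(points: np.ndarray) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= COLLINEAR_TOL if len(s) > 1 else True


@dataclass
class MarkerSet:
    """Reference (CT/model-frame) marker positions of one rigid body."""

    body_id: str
    markers: dict[str, np.ndarray]

    def __post_init__(self):
        self.markers = {m: np.asarray(p, dtype=float).reshape(3) for m, p in self.markers.items()}
        if len(self.markers) < 3:
            raise ValueError(f"body {self.body_id!r}: >= 3 markers required, got {len(self.markers)}")
        if _collinear(self.reference_array()):
            raise ValueError(f"body {self.body_id!r}: reference markers are collinear")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers)

    def reference_array(self, marker_ids=None) -> np.ndarray:
        ids = self.marker_ids if marker_ids is None else list(marker_ids)
        return np.stack([self.markers[m] for m in ids])


@dataclass
class TrajectorySet:
    """Per-frame observed 3D marker positions; NaN encodes missing frames."""

    frame_rate: float
    positions: dict[str, np.ndarray]

    def __post_init__(self):
        self.positions = {m: np.asarray(p, dtype=float).reshape(-1, 3) for m, p in self.positions.items()}
        lengths = {p.shape[0] for p in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError(f"markers have inconsistent frame counts: {sorted(lengths)}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.positions)

    def present(self, marker_id: str) -> np.ndarray:
        """Boolean mask of frames in which the marker was tracked."""
        return np.all(np.isfinite(self.positions[marker_id]), axis=1)

    def subset(self, marker_ids) -> "TrajectorySet":
        return TrajectorySet(self.frame_rate, {m: self.positions[m] for m in marker_ids})


@dataclass
class PoseSeries:
    """Per-frame pose of one body (model frame -> world) with rms residuals.

    Missing frames are NaN throughout.
    """

    body_id: str
    frame_rate: float
    rotations: np.ndarray  # (T, 3, 3)
    translations: np.ndarray  # (T, 3)
    rms_residual: np.ndarray  # (T,)

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.rotations).all(axis=(1, 2))

    def transform(self, frame: int) -> RigidTransform:
        if not self.valid[frame]:
            raise ValueError(f"body {self.body_id!r}: no pose at frame {frame}")
        return RigidTransform(self.rotations[frame], self.translations[frame])


@dataclass
class RigidityReport:
    """Outcome of the intermarker-distance screen for one marker pair."""

    pair: tuple[str, str]
    kind: str  # 'co-osseous' or 'cross-body'
    distances_mm: np.ndarray  # filtered series
    fluctuation_mm: float  # 5th-95th percentile range of the filtered series
    precision_mm: float
    k: float
    verdict: str = field(init=False)

    def __post_init__(self):
        if self.kind not in ("co-osseous", "cross-body"):
            raise ValueError(f"unknown pair kind {self.kind!r}")
        if self.fluctuation_mm <= self.k * self.precision_mm:
            self.verdict = "same-rigid-body"
        elif self.kind == "cross-body":
            self.verdict = "mobile-joint"
        else:
            self.verdict = "bending-suspected"


def kabsch(reference: np.ndarray, observed: np.ndarray):
    """Least-squares rigid transform mapping ``reference`` onto ``observed``.

    Returns ``(R, t, rms)`` minimizing sum |R p_i + t - q_i|^2, with a
    reflection guard (det(R) = +1). Both inputs are (N, 3), N >= 3.
    """
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(observed, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("kabsch needs matching (N>=3, 3) point sets")
    if _collinear(P):
        raise ValueError("reference markers are collinear; pose is unconstrained")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    resid = Q - (P @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rms


def _batched_kabsch(ref: np.ndarray, obs: np.ndarray):
    """Vectorized Kabsch over frames: ref (N,3), obs (T,N,3) all-finite."""
    pc = ref.mean(axis=0)
    P = ref - pc
    qc = obs.mean(axis=1)
    Q = obs - qc[:, None, :]
    H = np.einsum("ni,tnj->tij", P, Q)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    # absorb the reflection into the smallest singular direction
    V = Vt.transpose(0, 2, 1).copy()
    V[:, :, 2] *= d[:, None]
    R = np.einsum("tij,tkj->tik", V, U)
    t = qc - np.einsum("tij,j->ti", R, pc)
    fit = np.einsum("tij,nj->tni", R, ref) + t[:, None, :]
    rms = np.sqrt(np.mean(np.sum((obs - fit) ** 2, axis=2), axis=1))
    return R, t, rms


def fit_pose_series(ref: MarkerSet, obs: TrajectorySet) -> PoseSeries:
    """Fit the per-frame pose of one body from its tracked markers.

    Frames with fewer than 3 finite (and non-collinear) markers are output
    as missing (NaN). Raises if no frame at all can be fit.
    """
    shared = [m for m in ref.marker_ids if m in obs.positions]
    if len(shared) < 3:
        raise ValueError(f"body {ref.body_id!r}: fewer than 3 markers present in the trajectories")
    T = obs.n_frames
    traj = np.stack([obs.positions[m] for m in shared], axis=1)  # (T, N, 3)
    refpts = ref.reference_array(shared)

    rotations = np.full((T, 3, 3), np.nan)
    translations = np.full((T, 3), np.nan)
    rms = np.full(T, np.nan)

    finite = np.isfinite(traj).all(axis=2)  # (T, N)
    complete = finite.all(axis=1)
    if complete.any():
        R, t, r = _batched_kabsch(refpts, traj[complete])
        rotations[complete] = R
        translations[complete] = t
        rms[complete] = r
    for f in np.nonzero(~complete)[0]:
        idx = np.nonzero(finite[f])[0]
        if len(idx) < 3:
            continue
        sub = refpts[idx]
        if _collinear(sub):
            continue
        R, t, r = kabsch(sub, traj[f, idx])
        rotations[f], translations[f], rms[f] = R, t, r

    if not np.isfinite(rms).any():
        raise ValueError(f"body {ref.body_id!r}: no frame has >= 3 non-collinear markers")
    return PoseSeries(ref.body_id, obs.frame_rate, rotations, translations, rms)


def filter_pose_series(
    poses: PoseSeries,
    cutoff_hz: float = 1.5,
    order: int = 4,
    max_gap_s: float = 0.5,
) -> PoseSeries:
    """Low-pass filter a rigid-body transformation series.

    Translations and the nine rotation-matrix entries are zero-phase
    Butterworth filtered, and each filtered matrix is projected back onto
    SO(3) (nearest rotation by SVD). Interior gaps up to ``max_gap_s`` are
    bridged by spherical interpolation first; longer gaps and leading/
    trailing missing frames stay missing (only the contiguous tracked span
    is filtered).
    """
    from scipy.spatial.transform import Rotation, Slerp

    from .breath import lowpass_filter

    valid = poses.valid
    if not valid.any():
        raise ValueError(f"body {poses.body_id!r}: no valid frames to filter")
    idx = np.nonzero(valid)[0]
    first, last = idx[0], idx[-1]
    span = slice(first, last + 1)
    R = poses.rotations[span].copy()
    t = poses.translations[span].copy()
    gaps = ~valid[span]
    if gaps.any():
        runs = np.split(np.nonzero(gaps)[0], np.nonzero(np.diff(np.nonzero(gaps)[0]) > 1)[0] + 1)
        max_frames = int(round(max_gap_s * poses.frame_rate))
        for run in runs:
            if len(run) > max_frames:
                raise ValueError(
                    f"body {poses.body_id!r}: tracking gap of {len(run)} frames exceeds "
                    f"the {max_gap_s} s interpolation bound"
                )
            lo, hi = run[0] - 1, run[-1] + 1
            slerp = Slerp([lo, hi], Rotation.from_matrix(R[[lo, hi]]))
            R[run] = slerp(run).as_matrix()
            t[run] = np.column_stack([np.interp(run, [lo, hi], t[[lo, hi], j]) for j in range(3)])
    Rf = lowpass_filter(R.reshape(len(R), 9), cutoff_hz, poses.frame_rate, order).reshape(-1, 3, 3)
    U, _, Vt = np.linalg.svd(Rf)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    U[:, :, 2] *= d[:, None]
    Rf = np.einsum("tij,tjk->tik", U, Vt)
    tf = lowpass_filter(t, cutoff_hz, poses.frame_rate, order)

    rotations = np.full_like(poses.rotations, np.nan)
    translations = np.full_like(poses.translations, np.nan)
    rotations[span] = Rf
    translations[span] = tf
    return PoseSeries(poses.body_id, poses.frame_rate, rotations, translations, poses.rms_residual.copy())


def intermarker_distance(
    traj: TrajectorySet,
    a: str,
    b: str,
    filter_cutoff_hz: float | None = 1.5,
) -> np.ndarray:
    """Euclidean distance between two markers per frame, optionally low-pass filtered.

    Only the overlapping tracked span is used; the returned series has the
    trajectory's full length with NaN outside the overlap.
    """
    pa, pb = traj.positions[a], traj.positions[b]
    ok = np.all(np.isfinite(pa), axis=1) & np.all(np.isfinite(pb), axis=1)
    if not ok.any():
        raise ValueError(f"markers {a!r} and {b!r} share no tracked frames")
    d = np.full(traj.n_frames, np.nan)
    d[ok] = np.linalg.norm(pa[ok] - pb[ok], axis=1)
    if filter_cutoff_hz is None:
        return d
    from .breath import lowpass_filter

    idx = np.nonzero(ok)[0]
    first, last = idx[0], idx[-1]
    span = d[first : last + 1]
    if np.isnan(span).any():
        raise ValueError(f"markers {a!r}/{b!r}: interior tracking gaps; filter on the raw series instead")
    d[first : last + 1] = lowpass_filter(span, filter_cutoff_hz, traj.frame_rate)
    return d


def tracking_precision(traj: TrajectorySet, pairs: list[tuple[str, str]]):
    """Marker-tracking precision from co-osseous pairs.

    The precision statistic is the standard deviation of the *unfiltered*
    intermarker distance within each co-osseous pair; returns the mean,
    s.e.m. and count across pairs.
    """
    if not pairs:
        raise ValueError("at least one co-osseous pair is required")
    sds = []
    for a, b in pairs:
        d = intermarker_distance(traj, a, b, filter_cutoff_hz=None)
        d = d[np.isfinite(d)]
        if len(d) < 2:
            raise ValueError(f"pair ({a!r}, {b!r}) has fewer than 2 tracked frames")
        sds.append(float(np.std(d, ddof=1)))
    sds = np.asarray(sds)
    mean = float(sds.mean())
    sem = float(sds.std(ddof=1) / np.sqrt(len(sds))) if len(sds) > 1 else 0.0
    return mean, sem, len(sds)


def classify_rigidity(
    traj: TrajectorySet,
    a: str,
    b: str,
    kind: str,
    precision_mm: float,
    k: float = 2.0,
    filter_cutoff_hz: float = 1.5,
) -> RigidityReport:
    """Screen one marker pair: same rigid body, mobile joint, or bending?

    The fluctuation statistic is the 5th-95th percentile range of the
    low-pass-filtered distance series; the pair moves "as one bone" when
    that range stays within ``k`` times the tracking precision.
    """
    d = intermarker_distance(traj, a, b, filter_cutoff_hz=filter_cutoff_hz)
    dd = d[np.isfinite(d)]
    fluctuation = float(np.percentile(dd, 95) - np.percentile(dd, 5))
    return RigidityReport((a, b), kind, d, fluctuation, precision_mm, k)
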