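"""End-to-end orchestration: markers -> poses -> rigidity screen -> JCS
angles -> filtered, segmented, averaged cycles -> in vivo axes -> predicted
vs measured comparison.

The stage order mirrors the experimental workflow: fit rigid-body poses from
tracked markers, check the rigid-body model with the intermarker-distance
screen, attach joint coordinate systems at the zero pose (maximum
inhalation, resolved automatically from the expansion signal when not given),
extract ZYX Euler angles, low-pass filter, segment into breaths, resample to
100 phase points, average, take the peak-to-peak axis-angle per joint, and —
when vertebral landmarks are supplied — regress predicted against measured
axis orientations.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import breath
from .anatomical_axis import PredictedAxis, compute_axis
from .jcs import JCSFrames, JointAngleSeries, JointDefinition, build_jcs, extract_joint_angles
from .rigid_body import (
    MarkerSet,
    PoseSeries,
    RigidityReport,
    TrajectorySet,
    classify_rigidity,
    filter_pose_series,
    fit_pose_series,
    tracking_precision,
)

__all__ = ["AnalysisParams", "PipelineConfig", "PipelineResult", "run_pipeline", "interpolate_gaps"]


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with the study defaults."""

    cutoff_hz: float = 1.5
    filter_order: int = 4
    resample_points: int = 100
    min_peak_separation_s: float = 3.0
    rigidity_k: float = 2.0
    max_gap_s: float = 0.5  # longest tracking gap bridged by interpolation
    spline_smoothing: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.resample_points < 10:
            raise ValueError("resample_points must be >= 10")


@dataclass
class PipelineConfig:
    frame_rate: float
    joints: list[JointDefinition]
    zero_pose_frame: int | str = "auto"
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self):
        ids = [j.joint_id for j in self.joints]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate joint ids in config")


@dataclass
class PipelineResult:
    poses: dict[str, PoseSeries]
    precision_mm: float
    precision_sem_mm: float
    n_precision_pairs: int
    rigidity: list[RigidityReport]
    zero_pose_frame: int
    joint_angles: dict[str, JointAngleSeries]
    filtered_angles: dict[str, np.ndarray]
    breath_segments: list[tuple[int, int]]
    averaged: dict[str, breath.AveragedCycle]
    axes: dict[str, breath.InVivoAxis]
    predicted: dict[int, PredictedAxis] | None
    regression: pd.DataFrame | None
    provenance: dict

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.17g"

        rows = []
        for jid, ja in self.joint_angles.items():
            for f in range(ja.n_frames):
                rows.append((f, jid, *ja.angles_deg[f], *ja.translations_mm[f]))
        pd.DataFrame(rows, columns=["frame", "joint_id", "z_deg", "y_deg", "x_deg", "tx", "ty", "tz"]).to_csv(
            out / "joint_angles.csv", index=False, float_format=fmt
        )

        rows = []
        for jid, avg in self.averaged.items():
            for p in range(avg.mean_deg.shape[0]):
                rows.append((jid, p, *avg.mean_deg[p], *avg.sd_deg[p], avg.n_breaths))
        pd.DataFrame(
            rows,
            columns=["joint_id", "phase", "z_mean", "y_mean", "x_mean", "z_sd", "y_sd", "x_sd", "n_breaths"],
        ).to_csv(out / "averaged_cycles.csv", index=False, float_format=fmt)

        rows = []
        for jid, ax in self.axes.items():
            rows.append(
                (jid, ax.axis_angle.theta_deg, *ax.axis_angle.axis, *ax.plane_angles_deg, *ax.ternary, ax.degenerate)
            )
        pd.DataFrame(
            rows,
            columns=[
                "joint_id", "theta_deg", "axis_x", "axis_y", "axis_z",
                "sagittal_deg", "coronal_deg", "transverse_deg",
                "pct_x", "pct_y", "pct_z", "degenerate",
            ],
        ).to_csv(out / "in_vivo_axes.csv", index=False, float_format=fmt)

        pd.DataFrame(
            [
                (r.pair[0], r.pair[1], r.kind, r.fluctuation_mm, r.precision_mm, r.k, r.verdict)
                for r in self.rigidity
            ],
            columns=["marker_a", "marker_b", "kind", "fluctuation_mm", "precision_mm", "k", "verdict"],
        ).to_csv(out / "rigidity.csv", index=False, float_format=fmt)

        if self.regression is not None:
            self.regression.to_csv(out / "regression.csv", index=False, float_format=fmt)
        (out / "provenance.yaml").write_text(yaml.safe_dump(self.provenance, sort_keys=True))


def interpolate_gaps(series: np.ndarray, frame_rate: float, max_gap_s: float = 0.5) -> np.ndarray:
    """Linearly bridge interior NaN runs no longer than ``max_gap_s``.

    Longer gaps, and leading/trailing gaps, are left missing: an automatic
    rule bounded at half a second is reproducible, anything longer needs
    human judgement.
    """
    out = np.array(series, dtype=float)
    max_frames = int(round(max_gap_s * frame_rate))
    for col in out.T if out.ndim == 2 else [out]:
        bad = np.isnan(col)
        if not bad.any() or bad.all():
            continue
        idx = np.arange(len(col))
        runs = np.split(idx[bad], np.nonzero(np.diff(idx[bad]) > 1)[0] + 1)
        for run in runs:
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= len(col) or len(run) > max_frames:
                continue
            col[run] = np.interp(run, [lo, hi], [col[lo], col[hi]])
    return out


def _vertebra_of(joint_id: str) -> int | None:
    m = re.search(r"(\d+)$", joint_id)
    return int(m.group(1)) if m else None


def _expansion_signal(angle_blocks: list[np.ndarray]) -> np.ndarray:
    """PC1 score of the concatenated Euler traces of several joints."""
    X = np.hstack(angle_blocks)
    return breath.expansion_score(X)


def _coosseous_pairs(markersets: dict[str, MarkerSet]) -> list[tuple[str, str]]:
    pairs = []
    for ms in markersets.values():
        ids = ms.marker_ids
        pairs.extend((ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids)))
    return pairs


def _crossjoint_pairs(config: PipelineConfig, markersets: dict[str, MarkerSet]) -> list[tuple[str, str]]:
    # farthest marker from the anchor on each side: maximum lever arm, hence
    # the most sensitive pair for detecting relative motion across the joint
    pairs = []
    for j in config.joints:
        pair = []
        for body in (j.proximal_body_id, j.distal_body_id):
            ms = markersets[body]
            d = np.linalg.norm(ms.reference_array() - j.anchor, axis=1)
            pair.append(ms.marker_ids[int(np.argmax(d))])
        pairs.append(tuple(pair))
    return pairs


def _extract_all(
    config: PipelineConfig,
    poses: dict[str, PoseSeries],
    zero_frame: int,
) -> tuple[dict[str, JCSFrames], dict[str, JointAngleSeries]]:
    frames, angles = {}, {}
    for defn in config.joints:
        prox, dist = poses[defn.proximal_body_id], poses[defn.distal_body_id]
        jcs = build_jcs(defn, prox.transform(zero_frame), dist.transform(zero_frame))
        frames[defn.joint_id] = jcs
        angles[defn.joint_id] = extract_joint_angles(jcs, prox, dist, zero_pose_frame=zero_frame)
    return frames, angles


def run_pipeline(
    config: PipelineConfig,
    trajectories: TrajectorySet,
    markersets: dict[str, MarkerSet],
    landmarks=None,
    out_dir=None,
) -> PipelineResult:
    """Run the full analysis chain; see the module docstring for the stages."""
    p = config.params
    fs = config.frame_rate

    missing_bodies = {
        b for j in config.joints for b in (j.proximal_body_id, j.distal_body_id)
    } - set(markersets)
    if missing_bodies:
        raise ValueError(f"joint config references unknown bodies: {sorted(missing_bodies)}")

    raw_poses = {body: fit_pose_series(ms, trajectories) for body, ms in markersets.items()}
    # rigid-body transformations are themselves low-pass filtered before any
    # joint analysis; unfiltered poses keep the per-frame fit residuals
    poses = {
        body: filter_pose_series(ps, p.cutoff_hz, p.filter_order, p.max_gap_s)
        for body, ps in raw_poses.items()
    }

    co_pairs = _coosseous_pairs(markersets)
    precision, sem, n_pairs = tracking_precision(trajectories, co_pairs)
    rigidity = [
        classify_rigidity(trajectories, a, b, "co-osseous", precision, p.rigidity_k, p.cutoff_hz)
        for a, b in co_pairs
    ] + [
        classify_rigidity(trajectories, a, b, "cross-body", precision, p.rigidity_k, p.cutoff_hz)
        for a, b in _crossjoint_pairs(config, markersets)
    ]

    # zero pose: given, or the first inhalation peak of a provisional extraction
    all_valid = np.all([ps.valid for ps in poses.values()], axis=0)
    if not all_valid.any():
        raise ValueError("no frame has poses for every body")
    first_valid = int(np.argmax(all_valid))
    if config.zero_pose_frame == "auto":
        _, prov_angles = _extract_all(config, poses, first_valid)
        blocks = [
            interpolate_gaps(a.angles_deg, fs, p.max_gap_s) for a in prov_angles.values()
        ]
        if any(np.isnan(b).any() for b in blocks):
            raise ValueError("tracking gaps too long to bridge; supply zero_pose_frame explicitly")
        score = breath.lowpass_filter(_expansion_signal(blocks), p.cutoff_hz, fs, p.filter_order)
        segs = breath.segment_breaths(score, fs, p.min_peak_separation_s)
        zero_frame = segs[0][0] if segs else first_valid
        if not segs:
            warnings.warn("no inhalation peaks found; using the first valid frame as zero pose")
    else:
        zero_frame = int(config.zero_pose_frame)

    _, joint_angles = _extract_all(config, poses, zero_frame)

    filtered: dict[str, np.ndarray] = {}
    for jid, ja in joint_angles.items():
        a = interpolate_gaps(ja.angles_deg, fs, p.max_gap_s)
        if np.isnan(a).any():
            raise ValueError(f"joint {jid!r}: unbridgeable tracking gaps in the angle traces")
        filtered[jid] = breath.lowpass_filter(a, p.cutoff_hz, fs, p.filter_order)

    score = _expansion_signal(list(filtered.values()))
    segments = breath.segment_breaths(score, fs, p.min_peak_separation_s)
    if not segments:
        raise ValueError("no complete breathing cycle found in the trial")

    predicted = None
    if landmarks is not None:
        predicted = {}
        for lm in landmarks:
            predicted[lm.vertebra_id] = compute_axis(lm)

    averaged: dict[str, breath.AveragedCycle] = {}
    axes: dict[str, breath.InVivoAxis] = {}
    for jid, a in filtered.items():
        cycles = [
            breath.resample_cycle(a[s : e + 1], jid, s, e, p.resample_points)
            for s, e in segments
            if e - s + 1 >= 10
        ]
        if not cycles:
            warnings.warn(f"joint {jid!r}: no usable cycles; skipped")
            continue
        averaged[jid] = breath.average_cycles(cycles)
        reference = None
        defn = next(j for j in config.joints if j.joint_id == jid)
        if predicted and defn.archetype == "costovertebral":
            vid = _vertebra_of(jid)
            if vid in predicted:
                reference = predicted[vid].axis
        axes[jid] = breath.total_rotation_axis(
            averaged[jid], reference_axis=reference, smoothing=p.spline_smoothing
        )

    regression = None
    if predicted:
        pred_rows, meas_rows = [], []
        for defn in config.joints:
            if defn.archetype != "costovertebral" or defn.joint_id not in axes:
                continue
            vid = _vertebra_of(defn.joint_id)
            if vid not in predicted or axes[defn.joint_id].degenerate:
                continue
            pred_rows.append(predicted[vid].plane_angles)
            meas_rows.append(axes[defn.joint_id].plane_angles_deg)
        if len(pred_rows) >= 3:
            regression = breath.regress_predicted_vs_measured(
                np.stack(pred_rows), np.stack(meas_rows)
            )

    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("ribkin")
    except PackageNotFoundError:
        pkg_version = "unknown"
    config_doc = yaml.safe_dump(
        {
            "frame_rate": fs,
            "zero_pose_frame": config.zero_pose_frame,
            "params": vars(p).copy(),
            "joints": [j.joint_id for j in config.joints],
        },
        sort_keys=True,
    )
    provenance = {
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "seed": p.seed,
        "ribkin_version": pkg_version,
        "numpy_version": np.__version__,
        "zero_pose_frame": int(zero_frame),
        "n_breaths": len(segments),
    }

    result = PipelineResult(
        poses=poses,
        precision_mm=precision,
        precision_sem_mm=sem,
        n_precision_pairs=n_pairs,
        rigidity=rigidity,
        zero_pose_frame=zero_frame,
        joint_angles=joint_angles,
        filtered_angles=filtered,
        breath_segments=segments,
        averaged=averaged,
        axes=axes,
        predicted=predicted,
        regression=regression,
        provenance=provenance,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
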