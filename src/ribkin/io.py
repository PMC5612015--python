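"""File formats: marker-trajectory CSV (XMALab export dialect), marker-set
and landmark tables, and the YAML pipeline configuration.

Conventions fixed across all files: angles degrees, coordinates mm, frames
0-based, breathing-cycle phase points 0-99. Trajectory CSVs have one column
triplet per marker (``<marker>_X``, ``<marker>_Y``, ``<marker>_Z``), one row
per frame, blank cells for missing frames.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomical_axis import VertebralLandmarks
from .jcs import JointDefinition
from .rigid_body import MarkerSet, TrajectorySet

__all__ = [
    "ParseError",
    "read_trajectories",
    "write_trajectories",
    "read_markersets",
    "write_markersets",
    "read_landmarks",
    "write_landmarks",
    "read_joint_config",
    "write_joint_config",
    "run_pipeline",
]

#: full-precision float format so write -> read round-trips bit-exactly
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file did not match the expected dialect."""


def read_trajectories(path: str | Path, frame_rate: float) -> TrajectorySet:
    """Read a marker-trajectory CSV in the XMALab export dialect.

    Marker names are inferred from ``_X``/``_Y``/``_Z`` column triplets;
    blank or NaN cells become missing frames. A marker missing one of its
    three columns, or a non-numeric cell, is a :class:`ParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"{path}: {exc}") from exc
    suffix_of = {}
    for col in df.columns:
        if "_" not in col or col.rsplit("_", 1)[1] not in ("X", "Y", "Z"):
            raise ParseError(f"{path}: column {col!r} is not a <marker>_X/_Y/_Z column")
        name, suffix = col.rsplit("_", 1)
        suffix_of.setdefault(name, set()).add(suffix)
    for name, suffixes in suffix_of.items():
        missing = {"X", "Y", "Z"} - suffixes
        if missing:
            raise ParseError(f"{path}: marker {name!r} is missing column(s) {sorted(missing)}")
    positions = {}
    for name in suffix_of:
        cols = [f"{name}_{s}" for s in ("X", "Y", "Z")]
        try:
            arr = df[cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            bad = _first_bad_cell(df[cols])
            raise ParseError(f"{path}: non-numeric cell for marker {name!r} at data row {bad}") from exc
        # a frame is missing unless all three coordinates are present
        incomplete = np.isnan(arr).any(axis=1)
        arr[incomplete] = np.nan
        positions[name] = arr
    if not positions:
        raise ParseError(f"{path}: no marker columns found")
    return TrajectorySet(frame_rate, positions)


def _first_bad_cell(frame: pd.DataFrame) -> int:
    for i, (_, row) in enumerate(frame.iterrows()):
        for v in row:
            if isinstance(v, str):
                try:
                    float(v)
                except ValueError:
                    return i
    return -1


def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    data = {}
    for m in traj.marker_ids:
        for j, s in enumerate(("X", "Y", "Z")):
            data[f"{m}_{s}"] = traj.positions[m][:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_markersets(path: str | Path) -> dict[str, MarkerSet]:
    """Read reference marker positions: columns body_id, marker_id, x, y, z."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"body_id", "marker_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out = {}
    for body_id, grp in df.groupby("body_id", sort=False):
        if grp["marker_id"].duplicated().any():
            raise ParseError(f"{path}: duplicate marker ids for body {body_id!r}")
        markers = {r.marker_id: np.array([r.x, r.y, r.z]) for r in grp.itertuples()}
        out[str(body_id)] = MarkerSet(str(body_id), markers)
    return out


def write_markersets(bodies: dict[str, MarkerSet], path: str | Path) -> None:
    rows = [
        (body_id, m, *ms.markers[m])
        for body_id, ms in bodies.items()
        for m in ms.marker_ids
    ]
    pd.DataFrame(rows, columns=["body_id", "marker_id", "x", "y", "z"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_landmarks(path: str | Path) -> list[VertebralLandmarks]:
    """Landmark CSV: vertebra_id, side, landmark in {parapophysis, diapophysis}, x, y, z."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"vertebra_id", "side", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (vid, side), grp in df.groupby(["vertebra_id", "side"], sort=True):
        pts = {r.landmark: np.array([r.x, r.y, r.z]) for r in grp.itertuples()}
        if set(pts) != {"parapophysis", "diapophysis"}:
            raise ParseError(
                f"{path}: vertebra {vid} ({side}) needs exactly a parapophysis and a diapophysis"
            )
        out.append(VertebralLandmarks(int(vid), pts["parapophysis"], pts["diapophysis"], side=str(side)))
    return out


def write_landmarks(landmarks: list[VertebralLandmarks], path: str | Path) -> None:
    rows = []
    for lm in landmarks:
        rows.append((lm.vertebra_id, lm.side, "parapophysis", *lm.parapophysis))
        rows.append((lm.vertebra_id, lm.side, "diapophysis", *lm.diapophysis))
    pd.DataFrame(rows, columns=["vertebra_id", "side", "landmark", "x", "y", "z"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def _joint_to_dict(j: JointDefinition) -> dict:
    d = {
        "joint_id": j.joint_id,
        "archetype": j.archetype,
        "proximal_body_id": j.proximal_body_id,
        "distal_body_id": j.distal_body_id,
        "anchor": [float(v) for v in j.anchor],
    }
    if j.distal_axis_points is not None:
        d["distal_axis_points"] = [[float(v) for v in p] for p in j.distal_axis_points]
    if j.proximal_plane_points is not None:
        d["proximal_plane_points"] = [[float(v) for v in p] for p in j.proximal_plane_points]
    return d


def write_joint_config(model, script, zero_pose_frame: int, path: str | Path) -> None:
    """Write the pipeline configuration for a simulated dataset."""
    doc = {
        "frame_rate": float(script.frame_rate),
        "zero_pose_frame": int(zero_pose_frame),
        "analysis": {
            "cutoff_hz": 1.5,
            "filter_order": 4,
            "resample_points": 100,
            "min_peak_separation_s": 3.0,
            "rigidity_k": 2.0,
            "seed": int(script.seed),
        },
        "joints": [_joint_to_dict(j) for j in model.joints],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_joint_config(path: str | Path):
    """Read the YAML pipeline configuration; returns a PipelineConfig."""
    from .pipeline import AnalysisParams, PipelineConfig

    doc = yaml.safe_load(Path(path).read_text())
    joints = [
        JointDefinition(
            joint_id=j["joint_id"],
            archetype=j["archetype"],
            proximal_body_id=j["proximal_body_id"],
            distal_body_id=j["distal_body_id"],
            anchor=np.asarray(j["anchor"], dtype=float),
            distal_axis_points=np.asarray(j["distal_axis_points"], dtype=float)
            if "distal_axis_points" in j
            else None,
            proximal_plane_points=np.asarray(j["proximal_plane_points"], dtype=float)
            if "proximal_plane_points" in j
            else None,
        )
        for j in doc["joints"]
    ]
    params = AnalysisParams(**doc.get("analysis", {}))
    return PipelineConfig(
        frame_rate=float(doc["frame_rate"]),
        joints=joints,
        zero_pose_frame=doc.get("zero_pose_frame", "auto"),
        params=params,
    )


def run_pipeline(*args, **kwargs):
    """See :func:`ribkin.pipeline.run_pipeline` (re-exported here)."""
    from .pipeline import run_pipeline as _run

    return _run(*args, **kwargs)
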