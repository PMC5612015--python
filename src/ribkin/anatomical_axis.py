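"""Predicted costovertebral hinge axes from vertebral landmarks.

The bicapitate vertebral rib articulates with the vertebra at two facets:
the capitulum on the parapophysis (P) and the tuberculum on the diapophysis
(D). If the joint behaves as a hinge, the axis of rib rotation is the line
through the two facets,

    A = (D - P) / |D - P|,

expressed in the column-aligned frame (x medio-lateral, left positive;
y cranio-caudal along the column, caudal positive; z dorso-ventral, dorsal
positive). The relative |x| : |y| : |z| composition of A predicts the
relative contributions of pump-handle (x), calliper (y) and bucket-handle
(z) motion; its angles to the sagittal, coronal and transverse body planes
are directly comparable with the in vivo rotation axis measured by the
breath-analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rotations import vector_plane_angles

__all__ = [
    "VertebralLandmarks",
    "PredictedAxis",
    "compute_axis",
    "summarize_axes",
    "ternary_composition",
    "mirror_to_left",
    "align_principal_axes",
]

#: minimum parapophysis-diapophysis separation (mm) for a usable axis
LANDMARK_GUARD_MM = 0.5


@dataclass(frozen=True)
class VertebralLandmarks:
    """Parapophysis and diapophysis of one vertebra, column-aligned frame, mm."""

    vertebra_id: int
    parapophysis: np.ndarray
    diapophysis: np.ndarray
    side: str = "left"

    def __post_init__(self):
        object.__setattr__(self, "parapophysis", np.asarray(self.parapophysis, dtype=float).reshape(3))
        object.__setattr__(self, "diapophysis", np.asarray(self.diapophysis, dtype=float).reshape(3))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class PredictedAxis:
    """Predicted hinge axis of one costovertebral joint.

    ``ternary`` is (%x, %y, %z) of the absolute axis components (sums to
    100); ``plane_angles`` are degrees to the sagittal, coronal and
    transverse planes.
    """

    vertebra_id: int
    axis: np.ndarray
    ternary: np.ndarray
    plane_angles: np.ndarray


def ternary_composition(axis: np.ndarray) -> np.ndarray:
    """Relative percentages of the absolute x, y, z components (sum 100)."""
    a = np.abs(np.asarray(axis, dtype=float))
    return 100.0 * a / a.sum()


def compute_axis(lm: VertebralLandmarks) -> PredictedAxis:
    """Anatomical hinge-axis prediction for one vertebra.

    The axis is the normalized diapophysis-parapophysis vector; right-side
    landmarks are mirrored to the left convention first so one sign
    convention covers both sides.
    """
    P, D = lm.parapophysis, lm.diapophysis
    if lm.side == "right":
        P, D = mirror_to_left(P), mirror_to_left(D)
    v = D - P
    norm = float(np.linalg.norm(v))
    if norm <= LANDMARK_GUARD_MM:
        raise ValueError(
            f"vertebra {lm.vertebra_id}: parapophysis and diapophysis are "
            f"{norm:.3g} mm apart (< {LANDMARK_GUARD_MM} mm guard)"
        )
    axis = v / norm
    return PredictedAxis(lm.vertebra_id, axis, ternary_composition(axis), vector_plane_angles(axis))


def mirror_to_left(point: np.ndarray) -> np.ndarray:
    """Mirror a right-side point across the sagittal (YZ) plane."""
    p = np.asarray(point, dtype=float).copy()
    p[0] = -p[0]
    return p


def summarize_axes(axes_by_individual: dict[str, list[PredictedAxis]]) -> pd.DataFrame:
    """Mean ± s.d. ternary composition per joint across individuals.

    ``axes_by_individual`` maps individual id -> list of PredictedAxis.
    Returns a tidy frame with one row per vertebra: mean and sd of each
    ternary component and of each plane angle, plus n. Means are flagged
    (``renormalized``) if the component means drift from summing to 100 by
    more than 1e-6.
    """
    if not axes_by_individual:
        raise ValueError("no individuals supplied")
    rows = []
    by_joint: dict[int, list[PredictedAxis]] = {}
    for axes in axes_by_individual.values():
        for ax in axes:
            by_joint.setdefault(ax.vertebra_id, []).append(ax)
    for vid in sorted(by_joint):
        group = by_joint[vid]
        tern = np.stack([a.ternary for a in group])
        ang = np.stack([a.plane_angles for a in group])
        mean = tern.mean(axis=0)
        sd = tern.std(axis=0, ddof=1) if len(group) > 1 else np.zeros(3)
        asd = ang.std(axis=0, ddof=1) if len(group) > 1 else np.zeros(3)
        rows.append(
            {
                "vertebra_id": vid,
                "n": len(group),
                "pct_x_mean": mean[0], "pct_y_mean": mean[1], "pct_z_mean": mean[2],
                "pct_x_sd": sd[0], "pct_y_sd": sd[1], "pct_z_sd": sd[2],
                "sagittal_deg_mean": ang.mean(axis=0)[0],
                "coronal_deg_mean": ang.mean(axis=0)[1],
                "transverse_deg_mean": ang.mean(axis=0)[2],
                "sagittal_deg_sd": asd[0], "coronal_deg_sd": asd[1], "transverse_deg_sd": asd[2],
                "renormalized": bool(abs(mean.sum() - 100.0) > 1e-6),
            }
        )
    return pd.DataFrame(rows)


def align_principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + centroid aligning a vertebral landmark cloud to the column frame.

    Mimics a principal-axes registration: the direction of greatest spread
    (the column) maps to y, the second to z, the least to x, with the
    rotation forced proper (det +1). Returns ``(R, centroid)`` such that
    aligned = (points - centroid) @ R.T. Sign conventions along each axis
    are not anatomically resolvable from a point cloud alone and may need a
    flip supplied by the user.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - centroid)
    if s[1] <= 1e-9:
        raise ValueError("landmark cloud is degenerate (collinear); cannot align")
    # principal directions: Vt[0] (column) -> y, Vt[1] -> z, Vt[2] -> x
    R = np.stack([Vt[2], Vt[0], Vt[1]])
    if np.linalg.det(R) < 0:
        R[0] = -R[0]
    return R, centroid
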