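"""Joint coordinate systems and per-frame Euler angle extraction.

Four joint archetypes are supported, matching the joints of a tripartite
crocodylian rib:

* ``costovertebral`` (vertebra -> vertebral rib) and ``sternocostal``
  (sternum -> sternal rib): axes aligned with the body planes at the zero
  pose — Z dorso-ventral (dorsal positive, bucket-handle), Y cranio-caudal
  (caudal positive, calliper), X medio-lateral (left positive, pump-handle).
* ``dorsal_intracostal`` (vertebral -> intermediate rib) and
  ``ventral_intracostal`` (intermediate -> sternal rib): X along the long
  axis of the distal segment (long-axis rotation), Z in the plane of the
  proximal segment at the zero pose (abduction-adduction), Y = Z x X
  (depression-elevation). Right-handed throughout.

The zero pose is the frame of maximum inhalation: both JCS frames coincide
there (all angles and translations zero by construction), then each frame is
rigidly attached to its body and the per-frame relative rotation is
decomposed as intrinsic ZYX Euler angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rigid_body import PoseSeries
from .rotations import RigidTransform, batch_matrix_to_euler

__all__ = [
    "ARCHETYPES",
    "JointDefinition",
    "JCSFrames",
    "JointAngleSeries",
    "semantic_labels",
    "build_jcs",
    "extract_joint_angles",
]

ARCHETYPES = ("costovertebral", "sternocostal", "dorsal_intracostal", "ventral_intracostal")

_BODY_PLANE_LABELS = {"z": "bucket", "y": "calliper", "x": "pump"}
_INTRACOSTAL_LABELS = {"z": "abduction-adduction", "y": "depression-elevation", "x": "long-axis rotation"}


def semantic_labels(archetype: str) -> dict[str, str]:
    """Map each JCS rotation axis to the motion it measures."""
    if archetype in ("costovertebral", "sternocostal"):
        return dict(_BODY_PLANE_LABELS)
    if archetype in ("dorsal_intracostal", "ventral_intracostal"):
        return dict(_INTRACOSTAL_LABELS)
    raise ValueError(f"unknown joint archetype {archetype!r}")


@dataclass
class JointDefinition:
    """One joint: archetype, the two bodies, anchor point and axis data.

    ``anchor`` is the joint centre in world coordinates at the zero pose
    (for a costovertebral joint, the midpoint of parapophysis and
    diapophysis is the documented default). Intracostal archetypes
    additionally need ``distal_axis_points`` (two world points spanning the
    distal segment's long axis) and ``proximal_plane_points`` (three
    non-collinear world points in the proximal segment's plane), both at
    the zero pose.
    """

    joint_id: str
    archetype: str
    proximal_body_id: str
    distal_body_id: str
    anchor: np.ndarray
    zero_pose_frame: int = 0
    distal_axis_points: np.ndarray | None = None
    proximal_plane_points: np.ndarray | None = None

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown joint archetype {self.archetype!r}")
        if self.proximal_body_id == self.distal_body_id:
            raise ValueError(f"joint {self.joint_id!r}: proximal and distal bodies are the same")
        self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)
        if self.archetype.endswith("intracostal"):
            if self.distal_axis_points is None or self.proximal_plane_points is None:
                raise ValueError(
                    f"joint {self.joint_id!r}: intracostal archetypes need "
                    "distal_axis_points and proximal_plane_points"
                )
            self.distal_axis_points = np.asarray(self.distal_axis_points, dtype=float).reshape(2, 3)
            self.proximal_plane_points = np.asarray(self.proximal_plane_points, dtype=float).reshape(3, 3)


@dataclass
class JCSFrames:
    """A joint coordinate system attached to both bodies at the zero pose."""

    joint_id: str
    archetype: str
    R0: np.ndarray  # world orientation of the JCS at zero pose (columns X,Y,Z)
    attach_prox: np.ndarray  # body-frame orientation of the proximal-attached JCS
    attach_dist: np.ndarray
    anchor_prox: np.ndarray  # anchor in each body's model frame
    anchor_dist: np.ndarray
    labels: dict[str, str]


@dataclass
class JointAngleSeries:
    """Per-frame ZYX Euler angles (deg) and JCS translations (mm) of one joint."""

    joint_id: str
    archetype: str
    frame_rate: float
    angles_deg: np.ndarray  # (T, 3) columns z, y, x
    translations_mm: np.ndarray  # (T, 3) in the proximal JCS frame
    labels: dict[str, str]
    zero_pose_frame: int = 0

    @property
    def n_frames(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.angles_deg).all(axis=1)


def _orthonormalize(X: np.ndarray, Z_hint: np.ndarray) -> np.ndarray:
    """Frame with X given, Z = unit(Z_hint ⟂ X), Y = Z x X (right-handed)."""
    X = X / np.linalg.norm(X)
    Z = Z_hint - (Z_hint @ X) * X
    nz = np.linalg.norm(Z)
    if nz < 1e-9:
        raise ValueError("plane normal parallel to distal axis; JCS undefined")
    Z = Z / nz
    Y = np.cross(Z, X)
    R = np.column_stack([X, Y, Z])
    if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
        raise RuntimeError("JCS axes failed orthonormalization")
    return R


def _jcs_world_orientation(defn: JointDefinition) -> np.ndarray:
    if defn.archetype in ("costovertebral", "sternocostal"):
        # body planes of the column-aligned frame: X left, Y caudal, Z dorsal
        return np.eye(3)
    p0, p1 = defn.distal_axis_points
    X = p1 - p0
    if np.linalg.norm(X) < 1e-9:
        raise ValueError(f"joint {defn.joint_id!r}: degenerate distal axis points")
    a, b, c = defn.proximal_plane_points
    n = np.cross(b - a, c - a)
    if np.linalg.norm(n) < 1e-9:
        raise ValueError(f"joint {defn.joint_id!r}: proximal plane points are collinear")
    X = X / np.linalg.norm(X)
    # Z lies in the proximal plane and ⟂ X: n x X is in the plane and ⟂ both
    Z_hint = np.cross(n / np.linalg.norm(n), X)
    if np.linalg.norm(Z_hint) < 1e-9:
        raise ValueError(f"joint {defn.joint_id!r}: distal axis is normal to the proximal plane")
    # deterministic polarity: prefer dorsal-positive Z
    if Z_hint[2] < 0:
        Z_hint = -Z_hint
    return _orthonormalize(X, Z_hint)


def build_jcs(defn: JointDefinition, pose_prox: RigidTransform, pose_dist: RigidTransform) -> JCSFrames:
    """Attach one JCS to both bodies of a joint at the zero pose.

    ``pose_prox`` / ``pose_dist`` are the bodies' poses at
    ``defn.zero_pose_frame``; the two attached frames coincide there, so
    all extracted angles are zero at the zero pose by construction.
    """
    R0 = _jcs_world_orientation(defn)
    attach_prox = pose_prox.rotation.T @ R0
    attach_dist = pose_dist.rotation.T @ R0
    anchor_prox = pose_prox.inverse().apply(defn.anchor)
    anchor_dist = pose_dist.inverse().apply(defn.anchor)
    return JCSFrames(
        defn.joint_id, defn.archetype, R0, attach_prox, attach_dist,
        anchor_prox, anchor_dist, semantic_labels(defn.archetype),
    )


def extract_joint_angles(
    jcs: JCSFrames,
    prox: PoseSeries,
    dist: PoseSeries,
    zero_pose_frame: int = 0,
) -> JointAngleSeries:
    """Per-frame ZYX Euler angles and translations of distal relative to proximal.

    The joint rotation at frame t is Q_p(t)^-1 Q_d(t), where Q_b is the
    world orientation of the JCS frame attached to body b; the translation
    is the displacement of the distal-attached anchor from the
    proximal-attached anchor, expressed in the proximal JCS frame. Missing
    pose frames propagate as missing angle frames.
    """
    if prox.n_frames != dist.n_frames:
        raise ValueError(f"joint {jcs.joint_id!r}: pose series lengths differ")
    T = prox.n_frames
    angles = np.full((T, 3), np.nan)
    trans = np.full((T, 3), np.nan)
    ok = prox.valid & dist.valid
    if not ok.any():
        raise ValueError(f"joint {jcs.joint_id!r}: no overlapping pose frames")

    Rp = prox.rotations[ok] @ jcs.attach_prox  # (t,3,3) world orientation of prox JCS
    Rd = dist.rotations[ok] @ jcs.attach_dist
    Rj = np.einsum("tji,tjk->tik", Rp, Rd)  # Rp^T Rd
    angles[ok] = batch_matrix_to_euler(Rj)

    pd_w = np.einsum("tij,j->ti", dist.rotations[ok], jcs.anchor_dist) + dist.translations[ok]
    pp_w = np.einsum("tij,j->ti", prox.rotations[ok], jcs.anchor_prox) + prox.translations[ok]
    trans[ok] = np.einsum("tji,tj->ti", Rp, pd_w - pp_w)

    return JointAngleSeries(
        jcs.joint_id, jcs.archetype, prox.frame_rate, angles, trans,
        dict(jcs.labels), zero_pose_frame,
    )
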