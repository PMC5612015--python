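"""Exact 3D rotation algebra with ribcage-kinematics conventions.

All joint rotations in this package are intrinsic z-y'-x'' Euler angles
("ZYX" order): the matrix acting on column vectors is ``R = Rz @ Ry @ Rx``.
In the body-plane frame used throughout (x medio-lateral, left positive;
y cranio-caudal, caudal positive; z dorso-ventral, dorsal positive) the
z-rotation of a costovertebral joint is bucket-handle motion, y is calliper
motion and x is pump-handle motion.

Angles are degrees at every public surface; radians appear only inside
function bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerZYX",
    "AxisAngle",
    "RigidTransform",
    "validate_rotation_matrix",
    "euler_to_matrix",
    "matrix_to_euler",
    "batch_matrix_to_euler",
    "matrix_to_axis_angle",
    "axis_angle_to_matrix",
    "relative_rotation",
    "vector_plane_angles",
    "angle_between_deg",
]

#: tolerance on orthonormality / unit determinant of a rotation matrix
ORTHO_TOL = 1e-9
#: |sin(y)| beyond which the ZYX decomposition is treated as gimbal-locked
_GIMBAL_TOL = 1.0 - 1e-12


@dataclass(frozen=True)
class EulerZYX:
    """Intrinsic ZYX Euler triple, degrees.

    ``z_deg`` is the first (bucket / abduction) rotation, ``y_deg`` the
    second (calliper / elevation), ``x_deg`` the third (pump / long-axis).
    ``gimbal_lock`` marks triples extracted at |y| = 90 deg, where x was
    conventionally set to 0 and the degeneracy absorbed into z.
    """

    z_deg: float
    y_deg: float
    x_deg: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.z_deg, self.y_deg, self.x_deg], dtype=float)


@dataclass(frozen=True)
class AxisAngle:
    """A rotation as angle ``theta_deg`` >= 0 about a unit ``axis``.

    ``degenerate`` marks near-identity rotations whose axis is conventional
    rather than measured.
    """

    axis: np.ndarray
    theta_deg: float
    degenerate: bool = False

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))


@dataclass(frozen=True)
class RigidTransform:
    """Pose of one body at one frame: ``x_world = rotation @ x_model + translation``.

    Translation is millimetres.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        validate_rotation_matrix(R)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def rotation_about(point: np.ndarray, R: np.ndarray) -> "RigidTransform":
        """Rotation by ``R`` about a fixed ``point`` (the point is invariant)."""
        point = np.asarray(point, dtype=float)
        return RigidTransform(R, point - np.asarray(R) @ point)


def validate_rotation_matrix(R: np.ndarray, tol: float = ORTHO_TOL) -> np.ndarray:
    """Check R is a proper rotation (orthonormal, det +1) and return it as float array."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValueError("rotation matrix must be finite")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"matrix not orthonormal (max |R'R - I| = {err:.3g})")
    det = np.linalg.det(R)
    if abs(det - 1.0) > tol:
        raise ValueError(f"matrix is not a proper rotation (det = {det:.6g})")
    return R


def _euler_args(angles) -> np.ndarray:
    if isinstance(angles, EulerZYX):
        arr = angles.as_array()
    else:
        arr = np.asarray(angles, dtype=float).reshape(3)
    if not np.all(np.isfinite(arr)):
        raise ValueError("Euler angles must be finite")
    return arr


def euler_to_matrix(angles) -> np.ndarray:
    """Intrinsic ZYX Euler triple (degrees) -> 3x3 rotation matrix.

    ``angles`` is an :class:`EulerZYX` or a (z, y, x) sequence in degrees.
    """
    z, y, x = _euler_args(angles)
    return Rotation.from_euler("ZYX", [z, y, x], degrees=True).as_matrix()


def _wrap_deg(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def matrix_to_euler(R: np.ndarray) -> EulerZYX:
    """3x3 rotation matrix -> canonical intrinsic ZYX Euler triple (degrees).

    y is in [-90, 90]; z and x in (-180, 180]. At gimbal lock (|y| = 90 deg)
    only z ∓ x is determined: x is set to 0, the remainder absorbed into z,
    and the result flagged.
    """
    R = validate_rotation_matrix(R)
    sy = float(np.clip(-R[2, 0], -1.0, 1.0))
    y = np.degrees(np.arcsin(sy))
    if abs(sy) < _GIMBAL_TOL:
        z = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        x = np.degrees(np.arctan2(R[2, 1], R[2, 2]))
        return EulerZYX(_wrap_deg(z), y, _wrap_deg(x))
    # gimbal lock: with x := 0, R[0,1] = -sin z, R[1,1] = cos z for y = ±90
    z = np.degrees(np.arctan2(-R[0, 1], R[1, 1]))
    return EulerZYX(_wrap_deg(z), 90.0 if sy > 0 else -90.0, 0.0, gimbal_lock=True)


def batch_matrix_to_euler(R: np.ndarray) -> np.ndarray:
    """Vectorized ZYX extraction for a (T, 3, 3) stack; returns (T, 3) degrees.

    Same conventions as :func:`matrix_to_euler` (gimbal-locked frames get
    x = 0) but without per-frame validation or flags — the batch entry point
    for long pose series.
    """
    R = np.asarray(R, dtype=float)
    sy = np.clip(-R[:, 2, 0], -1.0, 1.0)
    y = np.degrees(np.arcsin(sy))
    locked = np.abs(sy) >= _GIMBAL_TOL
    z = np.degrees(np.arctan2(R[:, 1, 0], R[:, 0, 0]))
    x = np.degrees(np.arctan2(R[:, 2, 1], R[:, 2, 2]))
    if locked.any():
        z_lock = np.degrees(np.arctan2(-R[locked, 0, 1], R[locked, 1, 1]))
        z[locked] = z_lock
        x[locked] = 0.0
    return np.column_stack([z, y, x])


def matrix_to_axis_angle(
    R: np.ndarray,
    reference: np.ndarray | None = None,
    degenerate_tol_deg: float = 1e-7,
) -> AxisAngle:
    """Rotation matrix -> axis-angle with theta in [0, 180] degrees.

    The returned pair always reconstructs R (rotating by theta about axis).
    When the axis is compared with an anatomical axis it is a *line* and its
    sign is conventional: pass ``reference`` to report the sign making the
    dot product with that reference non-negative (this may invert the stored
    rotation, which consumers comparing orientations do not use), or apply
    :func:`canonical_axis_sign` downstream.
    """
    R = validate_rotation_matrix(R)
    rotvec = Rotation.from_matrix(R).as_rotvec()
    theta = float(np.linalg.norm(rotvec))
    theta_deg = np.degrees(theta)
    if theta_deg < degenerate_tol_deg:
        axis = np.array([1.0, 0.0, 0.0])
        if reference is not None:
            axis = np.asarray(reference, dtype=float)
            axis = axis / np.linalg.norm(axis)
        return AxisAngle(axis, theta_deg, degenerate=True)
    axis = rotvec / theta
    if reference is not None:
        axis = canonical_axis_sign(axis, reference)
    return AxisAngle(axis, theta_deg)


def canonical_axis_sign(axis: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Resolve the sign ambiguity of an axis (a line direction)."""
    axis = np.asarray(axis, dtype=float)
    if reference is not None:
        if float(axis @ np.asarray(reference, dtype=float)) < 0:
            return -axis
        return axis
    i = int(np.argmax(np.abs(axis)))
    return -axis if axis[i] < 0 else axis


def axis_angle_to_matrix(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rodrigues rotation: ``theta_deg`` degrees about unit ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
        raise ValueError(f"axis must be a unit vector (|axis| = {n:.6g})")
    return Rotation.from_rotvec(np.radians(theta_deg) * axis / n).as_matrix()


def relative_rotation(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Difference rotation Ra^-1 @ Rb, so that Ra @ result == Rb."""
    Ra = validate_rotation_matrix(Ra)
    Rb = validate_rotation_matrix(Rb)
    return Ra.T @ Rb


def vector_plane_angles(v: np.ndarray) -> np.ndarray:
    """Angles (degrees) between a unit vector and the three anatomical body planes.

    Returns ``(to sagittal YZ, to coronal XZ, to transverse XY)`` — i.e.
    arcsin of the |x|, |y| and |z| components — each in [0, 90]. The squared
    sines of the three angles sum to 1 for any unit vector.
    """
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
        raise ValueError(f"expected a unit vector, got |v| = {n:.6g}")
    return np.degrees(np.arcsin(np.clip(np.abs(v) / n, 0.0, 1.0)))


def angle_between_deg(u: np.ndarray, v: np.ndarray, directionless: bool = True) -> float:
    """Angle between two 3-vectors in degrees; by default sign-agnostic (lines)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    if directionless:
        c = abs(c)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
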