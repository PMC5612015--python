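"""Breath-cycle analysis: filtering, segmentation, cycle averaging and the
in vivo rotation axis.

Joint-angle traces are zero-phase Butterworth filtered (breathing at ~0.1 Hz
against a 1-2 Hz cutoff passes untouched while tracking jitter is removed),
segmented into inhalation-to-inhalation cycles, resampled to 100 points of
breathing-cycle phase and zeroed to the mean of each rotational degree of
freedom, then averaged pointwise across breaths.

The "total" rib rotation over a breath is the difference rotation between
the peak-inhalation and peak-exhalation orientations of the averaged cycle,
converted to axis-angle form. The axis's components, body-plane angles and
ternary composition are directly comparable with the anatomical hinge-axis
prediction; ordinary least squares regression of predicted against measured
plane angles quantifies how well bony morphology predicts motion.

Euler angles are never differenced componentwise: the two peak orientations
are reconstructed as rotation matrices first and the difference rotation is
taken at the matrix level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal

from .rotations import (
    AxisAngle,
    canonical_axis_sign,
    euler_to_matrix,
    matrix_to_axis_angle,
    relative_rotation,
    vector_plane_angles,
)
from .anatomical_axis import ternary_composition

__all__ = [
    "BreathCycle",
    "AveragedCycle",
    "InVivoAxis",
    "lowpass_filter",
    "segment_breaths",
    "expansion_score",
    "resample_cycle",
    "average_cycles",
    "total_rotation_axis",
    "regress_predicted_vs_measured",
]

RESAMPLE_POINTS = 100


@dataclass
class BreathCycle:
    """One inhalation-to-inhalation cycle resampled to phase points.

    ``angles_deg`` is (n_points, 3), columns z, y, x, zero-mean per column;
    ``mean_deg`` holds the subtracted means so orientations can be
    reconstructed exactly (Euler angles do not subtract, but the zeroing
    constant is recoverable).
    """

    joint_id: str
    start_frame: int
    end_frame: int
    angles_deg: np.ndarray
    mean_deg: np.ndarray


@dataclass
class AveragedCycle:
    """Pointwise mean ± s.d. across breath cycles of one joint."""

    joint_id: str
    mean_deg: np.ndarray  # (n_points, 3), zero-mean per column
    sd_deg: np.ndarray  # (n_points, 3)
    n_breaths: int
    mean_offset_deg: np.ndarray  # average of the cycles' subtracted means


@dataclass
class InVivoAxis:
    """Peak-to-peak ("total") rib rotation of one joint over the breath."""

    joint_id: str
    axis_angle: AxisAngle
    plane_angles_deg: np.ndarray
    ternary: np.ndarray
    peak_inhale_phase: int
    peak_exhale_phase: int
    degenerate: bool = False


def lowpass_filter(series: np.ndarray, cutoff_hz: float, frame_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter, DC gain 1.

    Applied along axis 0; NaN-free input required. The default 4th-order
    filter run forward and backward is effectively 8th order with no phase
    lag, the standard treatment for motion-capture traces.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff_hz < frame_rate / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={frame_rate / 2} Hz)")
    if np.isnan(series).any():
        raise ValueError("filter input contains NaN; restrict to the tracked span first")
    padlen = 3 * (2 * order + 1)
    if series.shape[0] <= padlen:
        raise ValueError(f"series too short to filter ({series.shape[0]} <= {padlen} samples)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def segment_breaths(
    expansion: np.ndarray,
    frame_rate: float,
    min_separation_s: float = 3.0,
    min_prominence_frac: float = 0.05,
) -> list[tuple[int, int]]:
    """Split a filtered expansion signal into inhalation-to-inhalation cycles.

    Cycle boundaries are successive inhalation peaks (local maxima of the
    expansion signal at least ``min_separation_s`` apart, with prominence at
    least ``min_prominence_frac`` of the signal's range). Returns a list of
    (start_frame, end_frame) pairs; empty, with a warning, if fewer than one
    complete cycle is present.
    """
    x = np.asarray(expansion, dtype=float)
    span = np.ptp(x)
    if span <= 0 or not np.isfinite(span):
        warnings.warn("expansion signal is flat; no breaths found")
        return []
    peaks, _ = signal.find_peaks(
        x,
        distance=max(1, int(round(min_separation_s * frame_rate))),
        prominence=min_prominence_frac * span,
    )
    if len(peaks) < 2:
        warnings.warn(f"fewer than one complete breathing cycle found ({len(peaks)} peaks)")
        return []
    return [(int(peaks[i]), int(peaks[i + 1])) for i in range(len(peaks) - 1)]


def expansion_score(angles_deg: np.ndarray, orient: np.ndarray | None = None) -> np.ndarray:
    """Scalar ribcage-expansion proxy: first principal component of the traces.

    The sign of a principal component is arbitrary; by default it is fixed
    so the largest-|loading| coefficient is positive. Pass ``orient`` (a
    3-vector) to orient the component along a known expansion direction
    instead (e.g. from generator ground truth).
    """
    X = np.asarray(angles_deg, dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc = Vt[0]
    if orient is not None:
        if pc @ np.asarray(orient, dtype=float) < 0:
            pc = -pc
    elif pc[np.argmax(np.abs(pc))] < 0:
        pc = -pc
    return Xc @ pc


def resample_cycle(
    angles_deg: np.ndarray,
    joint_id: str = "",
    start_frame: int = 0,
    end_frame: int | None = None,
    n_points: int = RESAMPLE_POINTS,
) -> BreathCycle:
    """Resample one cycle onto ``n_points`` equispaced phase points, zero the mean.

    ``angles_deg`` holds the frames of one inhalation-to-inhalation cycle
    (both boundary frames included), shape (n_frames, 3). Interpolation is
    linear in time; each point is 1/n_points of the breathing cycle.
    """
    A = np.asarray(angles_deg, dtype=float)
    if A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("cycle angles must be (n_frames, 3)")
    if A.shape[0] < 10:
        raise ValueError(f"cycle too short to resample ({A.shape[0]} frames)")
    if np.isnan(A).any():
        raise ValueError("cycle contains missing frames")
    phase_in = np.linspace(0.0, 1.0, A.shape[0])
    phase_out = np.linspace(0.0, 1.0, n_points)
    out = np.column_stack([np.interp(phase_out, phase_in, A[:, j]) for j in range(3)])
    mean = out.mean(axis=0)
    if end_frame is None:
        end_frame = start_frame + A.shape[0] - 1
    return BreathCycle(joint_id, start_frame, end_frame, out - mean, mean)


def average_cycles(cycles: list[BreathCycle]) -> AveragedCycle:
    """Pointwise mean and sample s.d. across breath cycles of one joint."""
    if not cycles:
        raise ValueError("no cycles to average")
    joint_ids = {c.joint_id for c in cycles}
    if len(joint_ids) > 1:
        raise ValueError(f"cycles from different joints: {sorted(joint_ids)}")
    shapes = {c.angles_deg.shape for c in cycles}
    if len(shapes) > 1:
        raise ValueError(f"cycles resampled to different lengths: {sorted(shapes)}")
    stack = np.stack([c.angles_deg for c in cycles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(cycles) > 1 else np.zeros_like(mean)
    offset = np.stack([c.mean_deg for c in cycles]).mean(axis=0)
    return AveragedCycle(cycles[0].joint_id, mean, sd, len(cycles), offset)


def total_rotation_axis(
    avg: AveragedCycle,
    reference_axis: np.ndarray | None = None,
    expansion_orient: np.ndarray | None = None,
    smoothing: float | None = None,
    degenerate_theta_deg: float = 0.5,
) -> InVivoAxis:
    """Axis-angle of the total rib rotation across the averaged breath.

    Peak inhalation and exhalation are the extrema of the expansion score
    (PC1 of the averaged traces, optionally spline-smoothed first). The two
    Euler triples are reconstructed as rotation matrices — with the zeroing
    offset restored, since Euler angles cannot be differenced componentwise
    — and the difference rotation is converted to axis-angle form. When a
    predicted anatomical axis is supplied the measured axis's sign is
    aligned to it (axes are lines; the dot product is made non-negative).
    """
    trace = avg.mean_deg.copy()
    # the first and last phase points sample the same breath event (the
    # inhalation boundary of an inhalation-to-inhalation cycle): close the
    # cycle by pooling them
    closure = 0.5 * (trace[0] + trace[-1])
    trace[0] = trace[-1] = closure
    if smoothing is not None:
        from scipy.interpolate import make_smoothing_spline

        phase = np.arange(trace.shape[0], dtype=float)
        trace = np.column_stack(
            [make_smoothing_spline(phase, trace[:, j], lam=smoothing)(phase) for j in range(3)]
        )
    score = expansion_score(trace, orient=expansion_orient)
    i_in = int(np.argmax(score))
    i_ex = int(np.argmin(score))
    e_in = trace[i_in] + avg.mean_offset_deg
    e_ex = trace[i_ex] + avg.mean_offset_deg
    R_rel = relative_rotation(euler_to_matrix(e_in), euler_to_matrix(e_ex))
    aa = matrix_to_axis_angle(R_rel, reference=reference_axis)
    if reference_axis is None and not aa.degenerate:
        # reported axes are lines: canonical sign, largest component positive
        aa = AxisAngle(canonical_axis_sign(aa.axis), aa.theta_deg)
    degenerate = aa.degenerate or aa.theta_deg < degenerate_theta_deg
    if degenerate:
        warnings.warn(
            f"joint {avg.joint_id!r}: total rotation {aa.theta_deg:.3g} deg is "
            "below the degeneracy threshold; axis orientation unreliable"
        )
    return InVivoAxis(
        avg.joint_id,
        aa,
        vector_plane_angles(aa.axis),
        ternary_composition(aa.axis),
        i_in,
        i_ex,
        degenerate=degenerate,
    )


def regress_predicted_vs_measured(
    predicted: dict[str, np.ndarray] | np.ndarray,
    measured: dict[str, np.ndarray] | np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS of measured on predicted plane angles, per body plane.

    Accepts either two (n, 3) arrays (columns sagittal, coronal,
    transverse) or two dicts mapping plane name -> paired 1-D arrays.
    Reports slope, intercept, R² and the slope-vs-zero p-value, plus
    identity-line departure tests (intercept != 0, slope != 1).
    """
    planes = ("sagittal", "coronal", "transverse")
    if measured is None:
        raise ValueError("both predicted and measured values are required")
    if isinstance(predicted, dict):
        pairs = {k: (np.asarray(predicted[k], float), np.asarray(measured[k], float)) for k in predicted}
    else:
        P = np.asarray(predicted, dtype=float)
        M = np.asarray(measured, dtype=float)
        if P.shape != M.shape or P.ndim != 2 or P.shape[1] != 3:
            raise ValueError("predicted and measured must both be (n, 3)")
        pairs = {planes[j]: (P[:, j], M[:, j]) for j in range(3)}
    rows = []
    for plane, (x, y) in pairs.items():
        if len(x) < 3 or len(x) != len(y):
            raise ValueError(f"plane {plane!r}: need >= 3 paired values")
        if np.ptp(x) <= 1e-12:
            raise ValueError(f"plane {plane!r}: predicted values are constant (degenerate design)")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = model.params
        rows.append(
            {
                "plane": plane,
                "n": len(x),
                "slope": float(slope),
                "intercept": float(intercept),
                "r_squared": float(model.rsquared),
                "p_slope": float(model.pvalues[1]),
                "p_intercept_nonzero": float(model.pvalues[0]),
                "p_slope_not_one": float(model.t_test("x1 = 1").pvalue),
            }
        )
    return pd.DataFrame(rows)
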