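# Methods

`ribkin` turns 3D marker trajectories from biplanar videoradiography into
joint kinematics for a breathing tripartite ribcage, and compares the
measured rotation axis of each vertebral rib with the hinge axis predicted
from costovertebral joint anatomy. This note records the models, the
parameters that matter, the numerical choices, and what the bundled
synthetic validation does and does not show.

## Coordinate conventions

All computations live in a column-aligned anatomical frame: x medio-lateral
(left positive), y cranio-caudal along the vertebral column (caudal
positive), z dorso-ventral (dorsal positive). Lengths are millimetres and
angles degrees at every public surface; radians appear only inside function
bodies. Frames are 0-based; breathing-cycle phase points run 0–99.

Joint rotations are intrinsic z–y′–x″ Euler angles ("ZYX"): the rotation
matrix acting on column vectors is `R = Rz·Ry·Rx`. For a costovertebral or
sternocostal joint whose axes coincide with the body planes, the z-rotation
is bucket-handle motion (rib shaft swinging laterally), y is calliper motion
(ribs splaying apart), and x is pump-handle motion (ventral rib end rising
cranially). For intracostal joints, x lies along the distal segment
(long-axis rotation), z lies in the proximal segment's plane at the zero
pose (abduction–adduction) and y completes the right-handed triad
(depression–elevation).

Canonical Euler ranges are y ∈ [−90°, 90°], z and x ∈ (−180°, 180°]. At
gimbal lock (|y| = 90°) only z ∓ x is determined; x is set to 0, the
remainder absorbed into z, and the triple flagged. An axis-angle pair always
reconstructs its rotation (θ ∈ [0°, 180°]); where an axis is compared with
an anatomical axis it is treated as a line, and its sign is chosen to make
the dot product with the reference non-negative (or, absent a reference, to
make the largest-magnitude component positive).

## The hinge-axis prediction

A bicapitate vertebral rib articulates at the parapophysis (P, receiving
the capitulum) and diapophysis (D, receiving the tuberculum). If the joint
is a hinge, the rotation axis is the line through the two facets,

    A = (D − P) / |D − P|.

The relative composition 100·|Aᵢ| / Σ|Aⱼ| predicts the relative
contributions of pump (x), calliper (y) and bucket (z) motion; the angles
between A and the sagittal (YZ), coronal (XZ) and transverse (XY) planes —
arcsin of |Ax|, |Ay|, |Az| — are the comparison surface against the
measured axis. Landmarks closer than 0.5 mm are rejected as degenerate.
Right-side landmarks are mirrored across the sagittal plane so one sign
convention covers both sides; the output notes this convention because
whether left and right landmarks should instead be averaged is a judgement
call the data alone cannot settle.

## From markers to joint angles

1. **Pose fitting.** Each bone (or declared group of two-to-three
   vertebrae, modelled as one rigid body to absorb vertebral flexion)
   carries ≥ 3 non-collinear markers with known CT-frame positions. The
   per-frame pose is the closed-form orthogonal Procrustes (Kabsch) fit with
   a reflection guard (det = +1) and uniform marker weights; frames with
   fewer than three usable markers are missing. The per-frame rms residual
   is reported.
2. **Pose filtering.** The fitted transformation series is low-pass
   filtered before any joint analysis: translations and the nine matrix
   entries pass through a zero-phase 4th-order Butterworth (cutoff 1.5 Hz by
   default, the midpoint of the 1–2 Hz range appropriate for ~0.1 Hz
   breathing), and each filtered matrix is projected back onto SO(3) by SVD.
   Filtering the poses, not just the extracted angles, matters: the joint
   coordinate systems are attached at a single zero-pose frame, and any
   unfiltered fit noise in that frame would propagate into every derived
   axis as a fixed conjugation. Interior tracking gaps up to 0.5 s are
   bridged (spherical interpolation for rotations, linear for translations);
   longer gaps stay missing, since bridging them is a judgement call.
3. **Rigidity screen.** Intermarker distances decide the rigid-body model.
   Tracking precision is the standard deviation of unfiltered co-osseous
   intermarker distances (mean ± s.e.m. across pairs). Each screened pair's
   filtered distance series is summarized by its 5th–95th percentile range —
   robust to single-frame outliers, which a max–min range is not — and
   compared with k × precision (k = 2 by default, operationalizing "within
   the range of tracking precision" as a ±2σ band): within the band, one
   rigid body; beyond it, a mobile joint for a cross-bone pair or suspected
   bending for a co-osseous pair. For cross-joint screening the marker
   farthest from the joint anchor is used on each side, because distance
   fluctuation scales with the lever arm. Note that isotropic per-marker
   noise σ inflates each distance by √2·σ, so the precision statistic
   estimates √2·σ, not σ.
4. **Joint coordinate systems.** At the zero pose — maximum inhalation,
   either given or resolved automatically as the first inhalation peak of
   the expansion signal — one orthonormal frame per joint is built in world
   space (body-plane axes for costovertebral/sternocostal; the
   distal-long-axis/proximal-plane construction for intracostal joints) and
   rigidly attached to both bodies, coincident at the user-supplied anchor
   (midpoint of P and D is the documented costovertebral default; the
   joint's true centre of rotation is not observable from osteology). Body
   planes are fixed, not tracked per-frame, so a tilted axis due to
   vertebral flexion shows up in the data rather than being silently
   absorbed. Per frame, the joint rotation is Q_prox⁻¹·Q_dist decomposed as
   ZYX angles; the translation is the distal anchor's displacement in the
   proximal JCS frame (reported, but no analysis depends on it). All angles
   and translations vanish at the zero pose by construction.
5. **Cycle analysis.** Angle traces are zero-phase Butterworth filtered,
   segmented at inhalation peaks (scipy peak-finding with a 3 s minimum
   separation and 5%-of-range prominence; breaths last ~10 s), and each
   inhalation-to-inhalation cycle is linearly resampled onto 100 phase
   points and zeroed to its per-component mean. The subtracted means are
   retained: Euler angles cannot be differenced componentwise, so any
   orientation reconstruction restores the offset first. Cycles are averaged
   pointwise (mean ± sample s.d.).
6. **The expansion signal.** "Maximum inhalation" needs an operational
   definition; the package uses the first principal component score of the
   Euler traces (concatenated across joints for segmentation, per joint for
   peak-picking), sign-oriented so the largest-|loading| coefficient is
   positive. For a symmetric breath waveform the inhale/exhale labelling of
   the two extrema is ambiguous, but the peak-to-peak axis-angle is
   label-invariant, so the derived axes do not depend on it; a configurable
   orientation vector covers asymmetric data.
7. **The in vivo axis.** Peak-inhalation and peak-exhalation phase points
   are located on the averaged cycle (whose duplicate endpoint samples —
   phases 0 and 99 are the same breath event — are pooled first; an optional
   cubic smoothing-spline pass is available but off by default). The two
   orientations are reconstructed as matrices, their difference rotation
   taken, and converted to axis-angle: the "total" rib rotation over the
   breath. Rotations below 0.5° are flagged degenerate — the axis of a
   near-identity rotation is numerically meaningless. Plane angles and
   ternary composition of the axis feed the predicted-vs-measured
   comparison; ordinary least squares per body plane reports slope,
   intercept, R² and identity-line departure tests (intercept ≠ 0,
   slope ≠ 1), with the joint grouping left to the caller.

## The synthetic ribcage

The generator emulates the study conditions end-to-end: eight tripartite
ribs (straight cylindrical segments, as crocodylian rib segments
approximately are — which deliberately makes long-axis rotation
observability depend on marker placement), vertebral sections of two
vertebrae, and a midline sternum. Defaults: 20 mm vertebral spacing,
25–35 mm rib segments, 3 markers per rib segment on ~3 mm posts, 4 per
vertebral section, 3 on the sternum (three being the minimum for pose
fitting), breath period 10 ± 1 s, 5 breaths, 100 frames/s, isotropic
Gaussian marker noise σ = 0.12 mm. A quarter-period lead-in and lead-out
bracket the scripted breaths so every inhalation peak is an interior
extremum the segmenter can find.

Landmark geometry is built from the target axis-composition profile:
joints 1–2 share a pump + bucket dominant composition (44/13/43), joints
3–8 interpolate to a calliper-dominant caudal profile (36/46/18), and the
parapophysis is placed at P = D − 14 mm·A, which realizes its lateral
migration from vertebra 3 caudally by construction. Per-joint motion is
scripted either as a hinge about a fixed axis or as independent Euler
amplitudes, with a raised-cosine waveform running from 0 at inhalation to
−amplitude at exhalation (optionally exhale-skewed). The default script
drives each costovertebral joint about its own anatomical axis
(amplitudes 10–18°, largest mid-ribcage) and gives the intracostal joints
amplitudes growing caudally from small cranial values — mirroring the in
vivo observation that the first dorsal intracostal joint barely moves. A
separate uniform-mobility script drives all intracostal joints at the
caudal end of that range, for validating the rigidity screen on motion
that is detectable everywhere. Everything the pipeline estimates is also
recorded as ground truth (poses, joint angles, axes, breath boundaries),
and noiseless trajectories are exactly consistent with the recorded poses.

What the synthetic data do **not** emulate: temporally correlated tracking
error, marker occlusion and mislabelling, curved rib geometry, soft-tissue
constraint between adjacent ribs, vertebral flexion by default (an optional
amplitude exists), and asymmetric or variable-depth breathing beyond period
jitter and the optional skew. Passing the bundled validation therefore
shows the *chain* is correct and noise-calibrated, not that real alligator
data would behave this well.

## Accuracy limits worth knowing

With three markers on a ~30 mm segment and σ = 0.12 mm, single-frame
orientation noise is ~2° about the segment's long axis (small lever arms),
falling to ~0.4° after filtering. The peak-difference axis estimate then
carries ~0.3° of noise in the difference rotation after averaging five
breaths, so the recovered axis direction is uncertain by roughly
0.3°/θ radians for a total rotation θ: ~1° for a well-excited mid-ribcage
joint (θ ≈ 18°), 2° or worse for weakly excited joints (θ ≲ 10°). The
error scales as 1/√(n breaths). Noiseless recovery is exact to ≪ 0.1°.
Consumers should treat axes from small rotations with proportionate
suspicion — the degenerate flag triggers only below 0.5°.

## Numerical choices

- Butterworth filters are 4th order, applied forward–backward (zero phase,
  effectively 8th order); DC gain is exactly 1 and the filter refuses
  series shorter than its padding length.
- Rotation validity means ‖RᵀR − I‖∞ ≤ 1e-9 and det R = 1 ± 1e-9;
  collinearity of a marker cloud means a second singular value ≤ 1e-6 mm.
- Resampling is linear in time; phase-locked cycles of different durations
  agree to interpolation error (< 0.1° at realistic sampling).
- OLS uses statsmodels; the slope = 1 test is a linear restriction t-test.
- Determinism: every stochastic element of the generator takes a mandatory
  seed; pipeline outputs are byte-identical across reruns of the same
  inputs, and provenance (config hash, seed, versions) is written alongside
  results.
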