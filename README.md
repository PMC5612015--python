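# ribkin

Rib kinematics from marker-based biplanar videoradiography (XROMM-style
data): from 3D marker trajectories and skeletal landmarks to
joint-coordinate-system Euler angles, anatomical hinge-axis predictions,
and axis-angle comparison of predicted against observed rib rotation —
with a ground-truthed synthetic ribcage simulator for end-to-end
validation.

## The problem

Crocodylians breathe with a mobile, tripartite ribcage: each thoracic rib
has an ossified vertebral segment and cartilaginous intermediate and
sternal segments, giving four joints per rib (costovertebral, dorsal and
ventral intracostal, sternocostal). The double-headed vertebral rib
articulates with the vertebra at two facets — capitulum on the
parapophysis, tuberculum on the diapophysis — so, if the joint behaves as
a hinge, its rotation axis should be the line through the two facets:

    A = (D − P) / |D − P|

in a column-aligned frame (x medio-lateral, y cranio-caudal, z
dorso-ventral). The relative |x| : |y| : |z| composition of **A** predicts
the mix of pump-handle (x), calliper (y) and bucket-handle (z) motion, and
because the parapophysis migrates from the centrum onto the transverse
process from the third thoracic vertebra, that mix should shift from
bucket-dominant cranially toward calliper-dominant caudally.

Testing this against in vivo data takes a chain of standard but
convention-laden steps: least-squares rigid-body pose fitting from
implanted markers, an intermarker-distance screen for what counts as one
rigid body, joint coordinate systems attached at maximum inhalation with
intrinsic ZYX Euler decomposition, zero-phase Butterworth filtering,
breath segmentation with 100-point phase normalization and cycle
averaging, and finally the peak-to-peak difference rotation converted to
axis-angle form for comparison (and OLS regression) against the
anatomical prediction. `ribkin` implements that chain as a library, a
small CLI, and a set of numbered analysis drivers, for anyone working with
marker-based skeletal kinematics of breathing.

## Worked example

The `analysis/` drivers run the whole study on a synthetic trial whose
ground truth is known. `01_simulate.py` builds the default eight-rib
ribcage, scripts five ~10 s breaths with each costovertebral joint hinging
about its own anatomical axis, and samples markers at 100 frames/s with
0.12 mm tracking noise:

```
$ python analysis/01_simulate.py
simulated 5610 frames (5 breaths at 100 Hz), 29 bodies, 32 joints
breath boundaries (frames): [250, 1285, 2367, 3400, 4269, 5360]
```

`02_rigidity_screen.py` estimates tracking precision from co-osseous
marker pairs and screens every pair (fluctuation is the 5th–95th
percentile range of the filtered intermarker distance, compared with twice
the precision):

```
tracking precision: 0.170 ± 0.000 mm (mean ± s.e.m., 99 co-osseous pairs)
kind        verdict
co-osseous  same-rigid-body    99
cross-body  mobile-joint       31
            same-rigid-body     1
```

All 99 within-bone pairs screen rigid; 31 of 32 joints are detected as
mobile. The one miss is the first dorsal intracostal joint, whose scripted
motion is deliberately tiny — with a ~3° excursion its intermarker
fluctuation stays inside the ±2σ precision band, exactly the situation in
which the screen *should* decline to call a joint mobile.

`03_anatomical_axes.py` computes the predicted axes: %bucket (z) falls
from 43% at joint 1 to 18% at joint 8 while %calliper (y) rises from 13%
to 46%, with %pump (x) roughly constant — the migration signature.
`04_joint_kinematics.py` and `05_axis_comparison.py` then recover the
in vivo axes from the noisy markers and regress measured on predicted
plane angles per body plane:

```
joint_id  theta_deg  pred_sagittal  meas_sagittal  pred_coronal  meas_coronal  pred_transverse  meas_transverse
    cv_1      10.14          44.41          46.75         11.93         11.96            43.14            40.77
    cv_4      18.01          43.22          42.51         28.20         29.53            33.69            33.24
    cv_8       9.25          36.08          35.43         48.81         49.98            17.13            16.15

     plane  n  slope  intercept  r_squared
  sagittal  8 1.0894    -3.8218     0.8964
   coronal  8 1.0338    -0.2609     0.9990
transverse  8 1.0311    -1.7612     0.9865
```

θ is the total (peak-inhalation to peak-exhalation) rib rotation per
breath. Because this trial's hinges *are* the anatomical axes, the
regressions sit near the identity line; residual scatter is what 0.12 mm
of marker noise does to an axis recovered from a 9–18° rotation. On real
data, systematic departures from the identity line — not scatter — are the
biologically interesting signal.

The same machinery is available as a CLI (`ribkin simulate / fit / axes /
compare / report`) operating on a dataset directory of trajectory,
marker, landmark and config files.

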