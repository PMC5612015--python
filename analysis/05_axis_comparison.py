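#!/usr/bin/env python
"""Predicted vs measured rib rotation axes.

Converts each costovertebral joint's averaged breath into an axis-angle
"total" rotation, compares its body-plane angles with the anatomical
prediction, and regresses measured on predicted per plane. With the trial's
hinges scripted about the anatomical axes the regressions should sit on the
identity line up to marker-noise scatter. Writes
results/axis_comparison.csv and results/axis_regression.csv.
"""

from pathlib import Path

import pandas as pd

from ribkin import io as rio
from ribkin.pipeline import _vertebra_of, run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "synthetic_trial"


def main() -> None:
    config = rio.read_joint_config(DATA / "pipeline_config.yaml")
    config.zero_pose_frame = "auto"
    traj = rio.read_trajectories(DATA / "trajectories.csv", config.frame_rate)
    markers = rio.read_markersets(DATA / "markers.csv")
    landmarks = rio.read_landmarks(DATA / "landmarks.csv")
    res = run_pipeline(config, traj, markers, landmarks=landmarks)

    rows = []
    for jid, ax in res.axes.items():
        if not jid.startswith("cv_"):
            continue
        pred = res.predicted[_vertebra_of(jid)]
        rows.append(
            {
                "joint_id": jid,
                "theta_deg": ax.axis_angle.theta_deg,
                "pred_sagittal": pred.plane_angles[0], "meas_sagittal": ax.plane_angles_deg[0],
                "pred_coronal": pred.plane_angles[1], "meas_coronal": ax.plane_angles_deg[1],
                "pred_transverse": pred.plane_angles[2], "meas_transverse": ax.plane_angles_deg[2],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "axis_comparison.csv", index=False)
    res.regression.to_csv(ROOT / "axis_regression.csv", index=False)
    print(df.round(2).to_string(index=False))
    print()
    print(res.regression.round(4).to_string(index=False))
    print(f"wrote {ROOT / 'axis_comparison.csv'} and {ROOT / 'axis_regression.csv'}")


if __name__ == "__main__":
    main()
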