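#!/usr/bin/env python
"""Predicted hinge axes from the costovertebral landmarks.

Computes the normalized diapophysis-parapophysis axis per vertebra, its
ternary composition (%pump : %calliper : %bucket) and its body-plane
angles, and writes results/predicted_axes.csv. Expect the cranial joints to
be pump + bucket dominant, with bucket giving way to calliper from joint 3
caudally as the parapophysis migrates onto the transverse process.
"""

from pathlib import Path

import pandas as pd

from ribkin import io as rio
from ribkin.anatomical_axis import compute_axis

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    landmarks = rio.read_landmarks(ROOT / "synthetic_trial" / "landmarks.csv")
    rows = []
    for lm in landmarks:
        ax = compute_axis(lm)
        rows.append(
            {
                "vertebra_id": ax.vertebra_id,
                "axis_x": ax.axis[0], "axis_y": ax.axis[1], "axis_z": ax.axis[2],
                "pct_pump_x": ax.ternary[0],
                "pct_calliper_y": ax.ternary[1],
                "pct_bucket_z": ax.ternary[2],
                "sagittal_deg": ax.plane_angles[0],
                "coronal_deg": ax.plane_angles[1],
                "transverse_deg": ax.plane_angles[2],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "predicted_axes.csv", index=False)
    print(df.round(2).to_string(index=False))
    print(f"wrote {ROOT / 'predicted_axes.csv'}")


if __name__ == "__main__":
    main()
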