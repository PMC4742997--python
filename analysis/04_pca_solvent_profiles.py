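#!/usr/bin/env python
"""PCA of the filtered solvent-study profiles.

Unit-variance scales the filtered feature intensities (log-transformed),
runs centered-SVD PCA, fits 95% confidence ellipses per solvent, and writes
scores / loadings / variance / ellipses CSVs under results/solvent_study/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from micromet.feature_io import read_feature_table
from micromet.multivariate import confidence_ellipse, pca_svd, unit_variance_scale

STUDY = Path(__file__).resolve().parents[1] / "results" / "solvent_study"


def main() -> None:
    table = read_feature_table(STUDY / "filtered_features.csv", STUDY / "filtered_metadata.csv")
    ids = table.sample_ids()
    matrix = np.log1p(table.intensities[ids].T.to_numpy())
    scaled, flagged = unit_variance_scale(matrix)
    if flagged.any():
        print(f"note: {int(flagged.sum())} constant feature column(s) zeroed before PCA")

    k = min(2, len(ids) - 1)
    res = pca_svd(scaled, k)
    cols = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(res.scores, index=pd.Index(ids, name="sample_id"), columns=cols)
    scores["condition"] = table.samples.loc[ids, "condition"].to_numpy()
    scores.to_csv(STUDY / "scores.csv")
    pd.DataFrame(res.loadings, index=pd.Index(table.feature_ids, name="feature_id"),
                 columns=cols).to_csv(STUDY / "loadings.csv")
    pd.DataFrame({"component": cols, "variance_explained": res.variance_explained}
                 ).to_csv(STUDY / "variance.csv", index=False)
    print("variance explained: "
          + ", ".join(f"{c}={v:.1%}" for c, v in zip(cols, res.variance_explained)))

    rows = []
    for condition in table.conditions:
        pts = scores.loc[scores["condition"] == condition, cols[:2]].to_numpy()
        if len(pts) < 3:
            continue
        e = confidence_ellipse(pts)
        rows.append({"condition": condition, "center_x": e.center[0], "center_y": e.center[1],
                     "semi_major": e.semi_axes[0], "semi_minor": e.semi_axes[1],
                     "angle_rad": e.angle_rad, "degenerate": e.degenerate})
        print(f"{condition}: score centroid ({e.center[0]:+.2f}, {e.center[1]:+.2f}), "
              f"95% ellipse semi-axes {e.semi_axes[0]:.2f} x {e.semi_axes[1]:.2f}")
    pd.DataFrame(rows).to_csv(STUDY / "ellipses.csv", index=False)
    print(f"wrote scores/loadings/variance/ellipses under {STUDY}")


if __name__ == "__main__":
    main()
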