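#!/usr/bin/env python
"""Visual summaries: PCA of the normalized matrix and heatmap ordering.

Computes SVD-based principal components over all analytes with 95%
concentration ellipses per group, and — for the analytes at raw p < 0.05
— standardizes columns and orders rows and columns by complete-linkage
clustering on Euclidean distances (the data behind a clustered heatmap).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from autoreact.differential import differential_table
from autoreact.preprocess import preprocess_pipeline
from autoreact.report import (
    concentration_ellipse,
    hclust_complete,
    pca,
    standardize_columns,
)
from autoreact.simdata import read_bead_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    dataset = read_bead_dataset(args.data)
    _, clean, normalized = preprocess_pipeline(dataset)
    groups = dataset.groups()
    X = normalized.values.loc[groups.index]

    pc = pca(X)
    pc1, pc2 = 100 * pc.variance_fraction[:2]
    print(f"PC1 {pc1:.2f}% / PC2 {pc2:.2f}% of total variance")
    pc.scores.iloc[:, :2].to_csv(args.out / "pca_scores.tsv", sep="\t")
    ellipses = {}
    for grp in ("case", "control"):
        ell = concentration_ellipse(pc.scores.loc[groups == grp].iloc[:, :2].to_numpy())
        ellipses[grp] = {
            "center": ell["center"].tolist(),
            "semi_axes": ell["semi_axes"].tolist(),
            "angle": ell["angle"],
        }
    (args.out / "pca_summary.json").write_text(json.dumps({
        "variance_pct": [float(pc1), float(pc2)], "ellipses": ellipses
    }, indent=2))

    diff = differential_table(
        normalized.values, clean.values, groups, dataset.analyte_meta
    )
    heat_cols = diff.index[diff["p_value"] < 0.05].tolist()
    if len(heat_cols) < 2:
        print("fewer than 2 analytes at raw p < 0.05; skipping heatmap ordering")
        return
    heat = standardize_columns(X[heat_cols])
    rows = hclust_complete(heat, axis=0)
    cols = hclust_complete(heat, axis=1)
    pd.DataFrame({"row_order": pd.Series(rows.order),
                  "col_order": pd.Series(cols.order)}).to_csv(
        args.out / "heatmap_ordering.tsv", sep="\t", index=False)
    print(f"heatmap: {len(heat_cols)} analytes at raw p < 0.05; "
          f"orderings -> {args.out / 'heatmap_ordering.tsv'}")


if __name__ == "__main__":
    main()
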