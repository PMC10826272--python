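#!/usr/bin/env python
"""Preprocess the bead-array cohort written by 01_simulate_cohort.py.

Builds the empty-well noise model, excludes below-noise analytes, merges
the technical replicates, subtracts background, and applies the weighted
Box-Cox + robust spline normalization pair.  Writes the clean (fold-
change scale) and normalized (testing scale) matrices plus a noise-model
report.
"""

import argparse
import json
from pathlib import Path

from autoreact.preprocess import preprocess_pipeline
from autoreact.simdata import read_bead_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    dataset = read_bead_dataset(args.data)
    noise, clean, normalized = preprocess_pipeline(dataset)
    args.out.mkdir(parents=True, exist_ok=True)
    clean.values.to_csv(args.out / "clean_matrix.tsv", sep="\t")
    normalized.values.to_csv(args.out / "normalized_matrix.tsv", sep="\t")
    (args.out / "noise_model.json").write_text(json.dumps({
        "threshold_rep1": noise.threshold_rep1,
        "threshold_rep2": noise.threshold_rep2,
        "outlier_analytes": sorted(noise.outlier_analytes),
        "excluded_analytes": sorted(noise.excluded_analytes),
        "rule": noise.rule,
    }, indent=2))
    print(f"high-background (sticky) analytes: {len(noise.outlier_analytes)}")
    print(f"below noise in both replicates, excluded: {len(noise.excluded_analytes)}")
    print(f"retained analytes: {clean.values.shape[1]}")
    print(f"anomalous replicate pairs flagged: {int(clean.provenance.to_numpy().sum())}")


if __name__ == "__main__":
    main()
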