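#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes a two-replicate bead-array dataset at the study design (30 XFG-like
cases vs 30 controls, 256 antigen fragments of which 7 carry true case
effects with log2 fold changes in 0.3-1.2) under results/cohort/.
"""

import argparse
from pathlib import Path

from autoreact.simdata import SimConfig, generate_bead_array, truth_set, write_bead_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    dataset = generate_bead_array(SimConfig(seed=args.seed))
    write_bead_dataset(dataset, args.out)
    print(f"wells x analytes: {dataset.mfi_rep1.shape[0]} x {dataset.mfi_rep1.shape[1]}")
    print(f"spiked (truth) analytes: {sorted(truth_set(dataset))}")
    print(f"dataset written to {args.out}/")


if __name__ == "__main__":
    main()
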