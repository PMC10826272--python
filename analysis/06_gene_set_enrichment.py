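#!/usr/bin/env python
"""Over-representation analysis of the significant-analyte genes.

Maps analytes with raw p < 0.05 to their gene symbols (the query is
deliberately broader than the corrected discovery list — ORA needs a
reasonably sized gene set), then tests each gene set of a GMT collection
with the hypergeometric tail against the panel's gene universe.  By
default scores a synthetic collection seeded with the truth genes; pass
--gmt to use a real collection.
"""

import argparse
from pathlib import Path

import pandas as pd

from autoreact.differential import differential_table
from autoreact.enrichment import map_analytes_to_genes, ora, parse_gmt, write_gmt
from autoreact.preprocess import preprocess_pipeline
from autoreact.simdata import generate_gene_sets, read_bead_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--gmt", type=Path, default=None, help="optional GMT file")
    ap.add_argument("--seed", type=int, default=1, help="seed for the synthetic collection")
    ap.add_argument("--out", type=Path, default=Path("results/ora.tsv"))
    args = ap.parse_args()

    dataset = read_bead_dataset(args.data)
    _, clean, normalized = preprocess_pipeline(dataset)
    diff = differential_table(
        normalized.values, clean.values, dataset.groups(), dataset.analyte_meta
    )
    query = map_analytes_to_genes(diff, alpha_raw=0.05)
    universe = sorted({g for gs in dataset.analyte_meta["genes"] for g in gs.split(";")})
    print(f"query: {len(query)} genes of a {len(universe)}-gene panel universe")

    if args.gmt:
        sets = parse_gmt(args.gmt)
    else:
        sets = generate_gene_sets(dataset, seed=args.seed)
        write_gmt(sets, args.out.parent / "gene_sets.gmt")
    table = ora(query, universe, sets)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t")
    sig = table[table["adj_p_value"] < 0.05]
    print(f"{len(sig)} of {len(table)} sets enriched at adj p < 0.05 -> {args.out}")
    print(table.head(8).round(4).to_string())


if __name__ == "__main__":
    main()
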