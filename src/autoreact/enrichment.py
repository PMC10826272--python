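"""Gene-set over-representation analysis (ORA).

A query gene list — here the genes of analytes with a raw p-value below a
threshold — is tested against each gene set of a GMT collection with the
one-sided hypergeometric tail: with a universe of N genes of which the
set covers K, and a query of n genes of which k land in the set,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

Raw p-values are BH-corrected across sets; results are sorted by the
enrichment ratio k/K (then p), the conventional ORA ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = ["GeneSetCollection", "parse_gmt", "write_gmt", "map_analytes_to_genes", "ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols upper-cased and deduplicated."""

    sets: dict  # name -> frozenset of gene symbols
    label: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def parse_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, member genes.

    Blank and duplicate genes within a line are dropped; a duplicated set
    name or a line with fewer than three fields is an error naming the
    line.
    """
    sets: dict = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        sets[name] = genes
    return GeneSetCollection(sets=sets, label=Path(path).stem)


def write_gmt(collection: GeneSetCollection | dict, path, description: str = "na") -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    lines = [
        "\t".join([name, description, *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def map_analytes_to_genes(
    diff: pd.DataFrame, alpha_raw: float = 0.05, use_adjusted: bool = False
) -> list:
    """Deduplicated genes of analytes below the significance threshold.

    ``diff`` is a differential table with a ``genes`` column (semicolon-
    joined symbols) and ``p_value`` / ``adj_p_value`` columns.  The
    default thresholds the *raw* p-value — ORA needs a reasonably sized
    query, so the query set is deliberately broader than the corrected
    discovery list.
    """
    if "genes" not in diff:
        raise ValueError("differential table lacks a 'genes' column")
    col = "adj_p_value" if use_adjusted else "p_value"
    hits = diff[diff[col] < alpha_raw]
    genes = sorted(
        {g.strip().upper() for gs in hits["genes"].dropna() for g in gs.split(";") if g.strip()}
    )
    if not genes:
        warnings.warn("no analyte passes the threshold; empty query gene list")
    return genes


def ora(query, universe, sets: GeneSetCollection | dict) -> pd.DataFrame:
    """Hypergeometric over-representation of the query within each set.

    Query genes outside the universe are dropped with a warning count;
    sets with no overlap with the universe (K = 0) are skipped.  Returns
    a table of (K, k, k/K ratio, raw p, BH-adjusted p) sorted by ratio
    descending then p ascending.
    """
    uni = {str(g).upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    q = {str(g).upper() for g in query}
    dropped = q - uni
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside the universe were dropped")
    q &= uni
    N, n = len(uni), len(q)

    collection = sets.sets if isinstance(sets, GeneSetCollection) else sets
    rows = []
    for name, members in collection.items():
        mem = {str(g).upper() for g in members}
        K = len(mem & uni)
        if K == 0:
            continue
        k = len(mem & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, k / K, p))
    table = pd.DataFrame(rows, columns=["set", "K", "k", "ratio", "p_value"]).set_index("set")
    if len(table):
        table["adj_p_value"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(["ratio", "p_value"], ascending=[False, True], kind="stable")
    else:
        table["adj_p_value"] = []
    return table
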