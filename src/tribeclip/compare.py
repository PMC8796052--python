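"""Cross-method target-set comparison and expression-bias analysis.

Target sets from different techniques (editing-based, crosslink-based,
external methylation maps) are compared as gene sets over a common
expressed-gene universe: exhaustive membership-pattern counts, nine
equal-frequency expression bins from log2(TPM+1), per-bin target
proportions, and splits of a target set by support from other sets.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd


def overlap_table(sets: dict[str, set], universe) -> pd.DataFrame:
    """Counts for every membership pattern of the sets within a universe.

    One row per pattern (including the all-absent complement); columns are
    one boolean per set plus ``count``.  Raises if a set contains a gene
    outside the universe.
    """
    universe = set(universe)
    for name, genes in sets.items():
        stray = set(genes) - universe
        if stray:
            raise ValueError(
                f"set {name!r} contains genes outside the universe: "
                f"{sorted(stray)[:5]}"
            )
    names = list(sets)
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        region = set(universe)
        for name, inside in zip(names, pattern):
            region &= sets[name] if inside else (universe - set(sets[name]))
        rows.append({**dict(zip(names, pattern)), "count": len(region)})
    return pd.DataFrame(rows)


def expression_bins(tpm: pd.Series, n_bins: int = 9) -> pd.Series:
    """Map expressed genes (TPM > 0) to equal-frequency expression bins.

    Genes are ordered by log2(TPM+1) with ties broken by stable gene-id
    order, then cut into ``n_bins`` equal-frequency bins of increasing
    expression (0 = lowest).  Raises on an empty or degenerate (all-equal)
    table.  Invariant under monotone relabeling of the TPM values.
    """
    if len(tpm) == 0:
        raise ValueError("empty expression table")
    expressed = tpm[tpm > 0]
    if len(expressed) == 0:
        raise ValueError("no expressed genes (TPM > 0)")
    if expressed.nunique() == 1:
        raise ValueError("degenerate expression table: all TPMs equal")
    x = np.log2(expressed.astype(float) + 1)
    order = x.sort_values(kind="stable").index
    ranks = pd.Series(np.arange(len(order)), index=order)
    bins = np.floor(ranks * n_bins / len(ranks)).astype(int)
    return bins.reindex(expressed.index).rename("bin")


def per_bin_target_proportion(target_genes, bins: pd.Series) -> pd.Series:
    """|targets in bin| / |bin| for each expression bin."""
    targets = set(target_genes)
    out = {}
    for b, genes in bins.groupby(bins):
        if len(genes) == 0:
            raise ValueError(f"empty expression bin {b}")
        out[b] = sum(g in targets for g in genes.index) / len(genes)
    return pd.Series(out, name="proportion").sort_index()


def support_split(
    target_genes, support_sets: dict[str, set], bins: pd.Series
) -> pd.DataFrame:
    """Split a target set by membership in the union of support sets.

    Returns per-bin proportions (within each part) for the supported and
    unsupported parts, plus the gene counts.
    """
    targets = list(dict.fromkeys(target_genes))
    union = set().union(*support_sets.values()) if support_sets else set()
    with_support = [g for g in targets if g in union]
    without = [g for g in targets if g not in union]
    rows = []
    for part, genes in (("with_support", with_support), ("without_support", without)):
        counts = bins.reindex(genes).dropna().astype(int).value_counts()
        total = max(len(genes), 1)
        for b in sorted(bins.unique()):
            rows.append(
                {
                    "part": part,
                    "bin": b,
                    "n_genes": int(counts.get(b, 0)),
                    "proportion": counts.get(b, 0) / total,
                }
            )
    return pd.DataFrame(rows)
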