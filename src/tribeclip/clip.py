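"""Post-processing of single-nucleotide crosslink sites from a peak caller.

Operates downstream of an upstream single-nucleotide peak caller: collapses
runs of directly adjacent peaks to the dominant (highest-scoring) one,
extends dominant peaks into 9-nt collapsed crosslink sites (CSS), splits
full-length-protein sites into IDR-dependent and IDR-independent sets by
proximity to truncated-protein sites, and computes site-level diagnostics
(nucleotide identity, metagene location, distance to the nearest editing
site).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeBundle, bin_of, FEATURES

logger = logging.getLogger("tribeclip")


def collapse_adjacent(sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse runs of directly adjacent peaks to the dominant peak.

    Directly adjacent means consecutive genomic positions on the same
    strand.  Within a run the peak with the highest score wins; score ties
    go to the 5'-most position (lowest coordinate on plus, highest on
    minus).  Idempotent.
    """
    if sites["score"].isna().any():
        raise ValueError("crosslink sites must carry scores")
    out = []
    for (chrom, strand), grp in sites.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos0")
        pos = grp["pos0"].to_numpy()
        run_id = np.concatenate([[0], np.cumsum(np.diff(pos) > 1)])
        for _, run in grp.groupby(run_id):
            scores = run["score"].to_numpy()
            best = np.flatnonzero(scores == scores.max())
            pick = best[-1] if strand == "-" else best[0]
            out.append(run.iloc[pick])
    return (
        pd.DataFrame(out)
        .sort_values(["chrom", "pos0", "strand"])
        .reset_index(drop=True)
    )


def make_css(
    sites: pd.DataFrame,
    ext: int = 4,
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Extend collapsed peaks by ``ext`` nt each side into CSS intervals.

    Each CSS is [pos-ext, pos+ext+1) (length 2*ext+1, 9 nt by default)
    centered on the dominant peak; intervals are clipped at contig edges
    and flagged in the ``clipped`` column.
    """
    out = sites.copy()
    start = out["pos0"] - ext
    end = out["pos0"] + ext + 1
    clipped = start < 0
    start = start.clip(lower=0)
    if contig_lengths is not None:
        limit = out["chrom"].map(contig_lengths)
        clipped |= end > limit
        end = np.minimum(end, limit)
    out["start"] = start
    out["end"] = end
    out["clipped"] = clipped
    if clipped.any():
        logger.warning("make_css: %d CSS clipped at contig edges", clipped.sum())
    return out


def _nearest_distance(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Unsigned genomic distance from each query site to the nearest
    reference site on the same chromosome and strand (inf if none)."""
    dist = np.full(len(query), np.inf)
    ref_groups = {
        key: np.sort(grp["pos0"].to_numpy())
        for key, grp in reference.groupby(["chrom", "strand"])
    }
    for key, grp in query.groupby(["chrom", "strand"]):
        ref = ref_groups.get(key)
        if ref is None or ref.size == 0:
            continue
        pos = grp["pos0"].to_numpy()
        idx = np.searchsorted(ref, pos)
        left = np.where(idx > 0, np.abs(pos - ref[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(
            idx < ref.size, np.abs(ref[np.minimum(idx, ref.size - 1)] - pos), np.inf
        )
        dist[grp.index.to_numpy()] = np.minimum(left, right)
    return dist


def split_idr_dependence(
    full_length: pd.DataFrame,
    truncated: pd.DataFrame,
    max_dist: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition full-length-protein sites by truncated-library support.

    A full-length site is IDR-independent iff a truncated-library site
    lies within ``max_dist`` nt (unsigned) on the same chromosome and
    strand; otherwise it is IDR-dependent.  Returns
    (idr_independent, idr_dependent); the partition is exhaustive.
    """
    full_length = full_length.reset_index(drop=True)
    dist = _nearest_distance(full_length, truncated)
    independent = dist <= max_dist
    return (
        full_length[independent].reset_index(drop=True),
        full_length[~independent].reset_index(drop=True),
    )


def nucleotide_proportions(sites: pd.DataFrame, bundle: GenomeBundle) -> pd.Series:
    """Strand-corrected nucleotide proportions at site positions (RNA)."""
    counts = dict.fromkeys("ACGU", 0)
    for chrom, pos, strand in zip(sites["chrom"], sites["pos0"], sites["strand"]):
        if not 0 <= pos < bundle.contig_length(chrom):
            raise IndexError(f"site {chrom}:{pos} out of bounds")
        base = bundle.fetch(chrom, pos, pos + 1, strand)
        counts[base.replace("T", "U")] += 1
    total = sum(counts.values())
    return pd.Series({b: c / total for b, c in counts.items()}, name="proportion")


def distance_to_nearest(
    query: pd.DataFrame, reference: pd.DataFrame, max_d: int = 200
) -> pd.DataFrame:
    """Cumulative proportion of query sites within d nt of a reference site.

    Distances are unsigned genomic nt on the same chromosome and strand.
    Returns a non-decreasing curve over d = 0..max_d.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("query and reference must be non-empty")
    dist = _nearest_distance(query.reset_index(drop=True), reference)
    d = np.arange(max_d + 1)
    cum = (dist[None, :] <= d[:, None]).mean(axis=1)
    return pd.DataFrame({"distance": d, "proportion": cum})


def metagene_profile(
    sites: pd.DataFrame,
    bundle: GenomeBundle,
    bins_per_feature: int = 10,
    n_background: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed/expected site enrichment along the gene body.

    Sites are annotated to (feature, bin) with ``bins_per_feature`` bins
    per 5'UTR/CDS/3'UTR; the expected distribution comes from a seeded
    random-position background over transcripts.  Uniformly placed sites
    give ratios near 1.
    """
    if len(sites) == 0:
        raise ValueError("empty site table")
    if "feature" not in sites.columns:
        sites = bundle.assign_genes(sites)
    obs = sites[sites["feature"].isin(FEATURES)]
    if len(obs) == 0:
        raise ValueError("no sites fall inside annotated gene-body features")
    rng = np.random.default_rng(seed)
    bg = bundle.random_transcript_positions(n_background, rng)
    index = pd.MultiIndex.from_product(
        [FEATURES, range(bins_per_feature)], names=["feature", "bin"]
    )

    def hist(df):
        key = pd.MultiIndex.from_arrays(
            [df["feature"], bin_of(df["rel_pos"].to_numpy(), bins_per_feature)]
        )
        return key.value_counts().reindex(index, fill_value=0).astype(float)

    o = hist(obs) / len(obs)
    e = hist(bg) / len(bg)
    ratio = o / e.replace(0, np.nan)
    out = pd.DataFrame({"observed": o, "expected": e, "enrichment": ratio})
    return out.reset_index()
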