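"""Differential A-to-I editing calls from fusion-vs-control base counts.

The caller takes per-sample base counts at candidate positions (any
position mismatching the reference in at least one sample), determines the
dominant alternative base per site, and tests whether the editing rate in
the fusion condition exceeds the control condition with a beta-binomial
score test (condition rates against the pooled rate, shared per-site
overdispersion estimated by the method of moments).  P-values are
Benjamini-Hochberg adjusted across all tested sites; significant calls
(adjusted p below alpha and log2 fold change above a floor) then pass
through the three post-filters:

1. the change must be A-to-G on the plus strand or T-to-C on the minus
   strand (the deaminase signature read through sequencing);
2. sites whose editing proportion in either condition is at or close to 1
   are removed as likely line-specific SNPs;
3. sites with summed fusion coverage below a read floor are removed.

Editing proportions are G/(A+G) on the plus strand and C/(T+C) on the
minus strand, i.e. alt/(alt+ref) on the genomic reference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genome import GenomeBundle
from .synthdata import BASES, EditingCounts

logger = logging.getLogger("tribeclip")

PSEUDO_LFC = 1e-3  # pseudocount on proportions in the log2 fold change


def editing_proportion(alt_count, ref_count) -> float:
    """alt/(alt+ref); 0 when both counts are 0 (no coverage)."""
    alt = np.asarray(alt_count, dtype=float)
    ref = np.asarray(ref_count, dtype=float)
    if (alt < 0).any() or (ref < 0).any():
        raise ValueError("counts must be non-negative")
    total = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, alt / np.where(total > 0, total, 1), 0.0)
    return float(out) if out.ndim == 0 else out


def _moment_rho(alt, cov, cond_p, groups):
    """Shared per-site overdispersion by the method of moments.

    Uses within-condition residual variance of per-sample proportions:
    Var(p_i) = p(1-p)(1/n_i + rho (1 - 1/n_i)).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(cov > 0, alt / np.where(cov > 0, cov, 1), np.nan)
    num = np.zeros(alt.shape[0])
    den = np.zeros(alt.shape[0])
    for mask, p in zip(groups, cond_p):
        p = np.clip(p, 1e-12, 1 - 1e-12)[:, None]
        resid = (prop[:, mask] - p) ** 2 - p * (1 - p) / np.maximum(cov[:, mask], 1)
        w = p * (1 - p) * (1 - 1 / np.maximum(cov[:, mask], 1))
        valid = cov[:, mask] > 0
        num += np.where(valid, resid, 0.0).sum(axis=1)
        den += np.where(valid, w, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    rho = np.clip(rho, 0.0, 0.5)
    # per-site moment estimates from ~10 samples are noisy and truncate at
    # zero; floor them at the pooled across-site estimate so sites with an
    # underestimated rho do not drive spurious significance
    pooled = float(np.clip(num.sum() / den.sum(), 0.0, 0.5)) if den.sum() > 0 else 0.0
    return np.maximum(rho, pooled)


def test_differential_editing(
    matrix: EditingCounts,
    min_support: int = 4,
    alpha: float = 0.01,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Call differential editing per site; returns all tested sites.

    Sites lacking a putative edit (alternative count >= 1) in at least
    ``min_support`` fusion samples are not tested.  The returned frame
    carries per-condition mean editing proportions, log2FC with a
    pseudocount, raw and BH-adjusted p-values, fusion coverage, and a
    ``significant`` flag (padj < alpha and log2FC > lfc_min).
    """
    fusion = matrix.condition_mask("fusion")
    control = matrix.condition_mask("control")
    if fusion.sum() < 2 or control.sum() < 2:
        raise ValueError("need at least two samples per condition")
    if min_support > fusion.sum():
        raise ValueError("min_support exceeds the number of fusion samples")

    counts = matrix.counts
    ref_idx = matrix.sites["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    totals = counts.sum(axis=1)  # (sites, 4)
    masked = totals.copy()
    masked[np.arange(len(masked)), ref_idx] = -1
    alt_idx = masked.argmax(axis=1)

    rows = np.arange(len(matrix))
    alt = counts[rows[:, None], np.arange(counts.shape[1])[None, :], alt_idx[:, None]]
    ref = counts[rows[:, None], np.arange(counts.shape[1])[None, :], ref_idx[:, None]]
    cov = alt + ref

    support = (alt[:, fusion] >= 1).sum(axis=1)
    any_cov = cov.sum(axis=1) > 0
    tested = (support >= min_support) & any_cov
    n_skip = int((~any_cov).sum())
    if n_skip:
        logger.info("skipping %d sites with zero coverage", n_skip)

    alt_t, ref_t, cov_t = alt[tested], ref[tested], cov[tested]
    ep_f = alt_t[:, fusion].sum(axis=1) / np.maximum(cov_t[:, fusion].sum(axis=1), 1)
    ep_c = alt_t[:, control].sum(axis=1) / np.maximum(
        cov_t[:, control].sum(axis=1), 1
    )
    ep_pool = alt_t.sum(axis=1) / np.maximum(cov_t.sum(axis=1), 1)

    rho = _moment_rho(alt_t, cov_t, (ep_f, ep_c), (fusion, control))
    # beta-binomial score test: difference of condition rates over its
    # null standard error, with the overdispersion inflating the variance
    # (Var(k_i) = n_i p(1-p)(1 + (n_i - 1) rho)); well calibrated at the
    # low per-sample counts typical of editing data
    p0 = np.clip(ep_pool, 1e-12, 1 - 1e-12)
    var = np.zeros(len(p0))
    for mask in (fusion, control):
        n_g = np.maximum(cov_t[:, mask].sum(axis=1), 1)
        infl = (cov_t[:, mask] * (1 + (cov_t[:, mask] - 1) * rho[:, None])).sum(axis=1)
        var += p0 * (1 - p0) * infl / n_g**2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (ep_f - ep_c) / np.sqrt(np.where(var > 0, var, 1)), 0.0)
    pvals = stats.norm.sf(z)

    log2fc = np.log2((ep_f + PSEUDO_LFC) / (ep_c + PSEUDO_LFC))
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals

    out = matrix.sites.loc[tested, ["chrom", "pos0", "strand", "ref"]].reset_index(
        drop=True
    )
    out["alt"] = np.array(list(BASES))[alt_idx[tested]]
    out["ep_fusion"] = ep_f
    out["ep_control"] = ep_c
    out["log2fc"] = log2fc
    out["pvalue"] = pvals
    out["padj"] = padj
    out["n_support"] = support[tested]
    out["cov_fusion"] = counts[tested][:, fusion, :].sum(axis=(1, 2))
    out["significant"] = (out["padj"] < alpha) & (out["log2fc"] > lfc_min)
    return out


def filter_calls(
    calls: pd.DataFrame,
    snp_threshold: float = 0.9,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Apply the three post-filters to significant editing calls.

    Keeps A->G on plus / T->C on minus; removes sites with an editing
    proportion in either condition at or above ``snp_threshold`` (likely
    SNPs); removes sites with summed fusion coverage below
    ``min_coverage``.
    """
    is_ag = (
        ((calls["ref"] == "A") & (calls["alt"] == "G") & (calls["strand"] == "+"))
        | ((calls["ref"] == "T") & (calls["alt"] == "C") & (calls["strand"] == "-"))
    )
    not_snp = (calls["ep_fusion"] < snp_threshold) & (
        calls["ep_control"] < snp_threshold
    )
    covered = calls["cov_fusion"] >= min_coverage
    kept = calls[is_ag & not_snp & covered].reset_index(drop=True)
    logger.info(
        "filter_calls: %d -> %d (A-to-G %d, SNP %d, coverage %d removed)",
        len(calls), len(kept), int((~is_ag).sum()), int((is_ag & ~not_snp).sum()),
        int((is_ag & not_snp & ~covered).sum()),
    )
    return kept


def annotate_sites(
    sites: pd.DataFrame, bundle: GenomeBundle, tpm: pd.Series | None = None
) -> pd.DataFrame:
    """Assign gene, gene-body feature, and relative position to sites.

    Overlapping-gene ties are broken by highest expression, then
    lexicographic gene id; sites outside genes get ``intergenic``.
    """
    return bundle.assign_genes(sites, tpm)


def edit_site_logo_matrix(
    sites: pd.DataFrame, bundle: GenomeBundle, flank: int = 2
) -> pd.DataFrame:
    """Nucleotide frequency matrix at and around edit sites (RNA alphabet).

    Rows A/C/G/U, columns -flank..+flank in transcript orientation; sites
    too close to a contig edge are skipped with a log message.
    """
    width = 2 * flank + 1
    counts = np.zeros((4, width))
    skipped = 0
    for chrom, pos, strand in zip(sites["chrom"], sites["pos0"], sites["strand"]):
        if pos - flank < 0 or pos + flank + 1 > bundle.contig_length(chrom):
            skipped += 1
            continue
        seq = bundle.fetch(chrom, pos - flank, pos + flank + 1, strand)
        for j, base in enumerate(seq):
            k = "ACGT".find(base)
            if k >= 0:
                counts[k, j] += 1
    if skipped:
        logger.info("logo matrix: skipped %d sites at contig edges", skipped)
    total = counts.sum(axis=0)
    freqs = counts / np.where(total > 0, total, 1)
    return pd.DataFrame(
        freqs, index=list("ACGU"), columns=range(-flank, flank + 1)
    )


def sample_editing_proportions(
    calls: pd.DataFrame, matrix: EditingCounts
) -> pd.DataFrame:
    """Per-sample editing proportions at the called sites (sites x samples)."""
    key = pd.MultiIndex.from_frame(matrix.sites[["chrom", "pos0", "strand"]])
    want = pd.MultiIndex.from_frame(calls[["chrom", "pos0", "strand"]])
    loc = key.get_indexer(want)
    if (loc < 0).any():
        raise KeyError("calls contain sites absent from the matrix")
    bidx = {b: i for i, b in enumerate(BASES)}
    ref_idx = calls["ref"].map(bidx).to_numpy()
    alt_idx = calls["alt"].map(bidx).to_numpy()
    sub = matrix.counts[loc]
    alt = sub[np.arange(len(loc)), :, alt_idx]
    ref = sub[np.arange(len(loc)), :, ref_idx]
    ep = editing_proportion(alt, ref)
    return pd.DataFrame(ep, columns=matrix.samples["sample"].to_list())


def pca_editing(calls: pd.DataFrame, matrix: EditingCounts, n_components: int = 2):
    """PCA of raw per-sample editing proportions at significant sites.

    Returns (scores, explained_variance_ratio); scores has one row per
    sample with its condition label.
    """
    if len(calls) < 2 or len(matrix.samples) < 2:
        raise ValueError("need at least two sites and two samples")
    ep = sample_editing_proportions(calls, matrix).to_numpy().T  # samples x sites
    if np.allclose(ep.std(axis=0), 0):
        raise ValueError("editing proportions are constant across samples")
    n_components = min(n_components, min(ep.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(ep - ep.mean(axis=0))
    out = matrix.samples[["sample", "condition"]].copy()
    for k in range(n_components):
        out[f"PC{k + 1}"] = scores[:, k]
    return out, pca.explained_variance_ratio_


def adar_correlation(
    calls: pd.DataFrame,
    matrix: EditingCounts,
    shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site Pearson correlation of editing proportion with ADAR TPM.

    Computed within each condition; a shuffled background scrambles the
    TPM vector ``shuffles`` times per condition.  Sites with a constant
    editing or TPM vector report a missing correlation.
    """
    ep = sample_editing_proportions(calls, matrix).to_numpy()
    rng = np.random.default_rng(seed)
    frames = []
    for condition in ("fusion", "control"):
        mask = matrix.condition_mask(condition)
        if mask.sum() < 3:
            raise ValueError("need at least three samples per condition")
        tpm = matrix.samples.loc[mask, "adar_tpm"].to_numpy(dtype=float)
        sub = ep[:, mask]
        frames.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "kind": "observed",
                    "r": _rowwise_pearson(sub, tpm),
                }
            )
        )
        for _ in range(shuffles):
            frames.append(
                pd.DataFrame(
                    {
                        "condition": condition,
                        "kind": "shuffled",
                        "r": _rowwise_pearson(sub, rng.permutation(tpm)),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _rowwise_pearson(mat: np.ndarray, vec: np.ndarray) -> np.ndarray:
    vc = vec - vec.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((mc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ vc) / np.where(denom > 0, denom, np.nan)
    return r


def coexpression_editing(
    target_max_ep: pd.Series,
    sc_matrix: pd.DataFrame,
    reader_gene: str,
    expressed_threshold: float = 0.0,
) -> pd.DataFrame:
    """Coexpression-with-reader proportion per target, joined to max EP.

    coexpression = (# cells expressing reader AND target) /
    (# cells expressing target); "expressing" means count above
    ``expressed_threshold``.  Targets expressed in zero cells report a
    missing proportion.
    """
    if reader_gene not in sc_matrix.index:
        raise KeyError(f"reader gene {reader_gene!r} absent from matrix")
    reader = sc_matrix.loc[reader_gene].to_numpy() > expressed_threshold
    rows = []
    for gene, max_ep in target_max_ep.items():
        if gene not in sc_matrix.index:
            rows.append((gene, np.nan, max_ep))
            continue
        expr = sc_matrix.loc[gene].to_numpy() > expressed_threshold
        n = int(expr.sum())
        co = np.nan if n == 0 else float((expr & reader).sum()) / n
        rows.append((gene, co, max_ep))
    return pd.DataFrame(rows, columns=["gene_id", "coexpression", "max_ep"])
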