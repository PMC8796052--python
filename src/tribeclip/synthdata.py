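"""Seeded generator for synthetic genomes, sites, and editing count tables.

The generator emulates the data layout and statistical structure that the
downstream analysis assumes:

* an annotated toy genome in which every gene is a contiguous
  5'UTR -> CDS -> 3'UTR transcript on a random strand;
* methylation (m6A) sites planted preferentially in 3'UTRs, each sitting on
  the A of a DRACH or GGAU island flanked by U/Y-rich tracts (UNUNU and
  UUUUU upstream, YYYYY downstream, optionally URUAY upstream);
* protein-RNA crosslink sites displaced a few nucleotides 5' of their m6A,
  planted on a uridine, with caller-style scores;
* fusion-vs-control per-sample base-count tables in which edited sites show
  low editing proportions with beta-binomial noise, background positions
  show sequencing-error-level mismatches, and a small number of
  line-specific SNP artifacts have editing proportions near 1;
* per-gene expression (TPM) tables and a binary single-cell expression
  matrix coupling target genes to the reader gene.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.default_rng`` streams, so generation is bit-reproducible.
Truth tables (true m6A sites, true crosslink sites, true target genes) are
returned alongside the observable files and are never encoded in them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBundle, make_site_table, revcomp

logger = logging.getLogger("tribeclip")

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class FlankElement:
    """A motif planted at a fixed transcript-strand offset from the m6A.

    ``offset`` is the signed position of the motif *start* relative to the
    methylated A (negative = 5').  An element with offset -15 and length 5
    therefore spans offsets -15..-11.  ``prob`` is the per-site planting
    probability.
    """

    pattern: str
    offset: int
    prob: float = 1.0


def default_flank_model() -> list[FlankElement]:
    return [
        FlankElement("UNUNU", -15, 0.8),
        FlankElement("UUUUU", -25, 0.5),
        FlankElement("URUAY", -21, 0.3),
        FlankElement("YYYYY", 8, 0.8),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Lengths are (low, high) bounds for uniform integer draws. Base
    frequencies default to a U-rich transcriptome-like composition.
    ``ep_target``/``ep_background`` are the true editing proportions at
    planted edit sites and the background mismatch rate; ``bb_overdispersion``
    is the beta-binomial rho.  ``snp_fraction`` controls how many artifact
    positions with editing proportion near 1 are planted (as a fraction of
    the number of true sites), each confined to one line group.
    """

    n_genes: int = 200
    target_fraction: float = 0.3
    utr5_len: tuple[int, int] = (50, 150)
    cds_len: tuple[int, int] = (300, 900)
    utr3_len: tuple[int, int] = (150, 400)
    spacer_len: tuple[int, int] = (100, 400)
    n_chroms: int = 2
    base_freqs: tuple[float, float, float, float] = (0.273, 0.165, 0.173, 0.389)
    m6a_rate: float = 3.0
    at_site_motifs: tuple[tuple[str, float], ...] = (("DRACH", 0.8), ("GGAU", 0.2))
    flank_model: list[FlankElement] = field(default_factory=default_flank_model)
    crosslink_offset_mean: float = -11.0
    crosslink_offset_sd: float = 4.0
    crosslink_prob: float = 0.8
    n_fusion: int = 5
    n_control: int = 5
    coverage_mean: float = 50.0
    ep_target: float = 0.25
    ep_background: float = 0.01
    bb_overdispersion: float = 0.01
    snp_fraction: float = 0.05
    n_cells: int = 500
    reader_cell_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.min() < 0 or freqs.max() > 1 or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("base_freqs must lie in [0,1] and sum to 1")
        if not 0 <= self.ep_background < self.ep_target <= 1:
            raise ValueError("require 0 <= ep_background < ep_target <= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        margin = self._margin()
        if self.utr3_len[0] <= 2 * margin:
            raise ValueError(
                f"3'UTR lengths {self.utr3_len} cannot fit the motif plan "
                f"(needs > {2 * margin} nt)"
            )

    def _margin(self) -> int:
        """Flank extent the motif plan needs on each side of an m6A site."""
        ext = 5
        for el in self.flank_model:
            ext = max(ext, abs(el.offset) + len(el.pattern))
        return ext + 5  # room for crosslink displacement


def _draw_seq(rng: np.random.Generator, n: int, freqs) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=list(freqs))


def _realize_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern.upper())


def simulate_genome(config: SimConfig):
    """Generate a genome bundle plus truth tables.

    Returns
    -------
    bundle : GenomeBundle
    truth : dict with keys ``m6a`` (SiteTable), ``crosslinks`` (SiteTable
        with scores), ``targets`` (list of gene ids), ``tpm`` (Series).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    margin = config._margin()

    gene_rows = []
    m6a_rows = []
    cl_rows = []
    chrom_parts: list[list[str]] = [[] for _ in range(config.n_chroms)]
    chrom_cursor = [0] * config.n_chroms

    at_names = [m for m, _ in config.at_site_motifs]
    at_probs = np.asarray([p for _, p in config.at_site_motifs])
    at_probs = at_probs / at_probs.sum()

    for g in range(config.n_genes):
        gid = f"G{g:04d}"
        u5 = int(rng.integers(*config.utr5_len))
        cds = int(rng.integers(*config.cds_len))
        u3 = int(rng.integers(*config.utr3_len))
        tlen = u5 + cds + u3
        sense = _draw_seq(rng, tlen, config.base_freqs).astype("U1")

        is_target = rng.random() < config.target_fraction
        n_sites = rng.poisson(config.m6a_rate) if is_target else 0
        # transcript coordinates of planted m6A sites, inside the 3'UTR
        lo, hi = u5 + cds + margin, tlen - margin
        site_ts: list[int] = []
        if n_sites > 0 and hi > lo:
            cand = rng.permutation(np.arange(lo, hi))
            for t in cand:
                # keep whole motif plans disjoint between neighboring sites
                if all(abs(t - s) > margin for s in site_ts):
                    site_ts.append(int(t))
                if len(site_ts) == n_sites:
                    break
        # planting passes: flanks first, at-site cores second (cores win any
        # overlap between neighboring plans), crosslinks last avoiding cores
        site_ts = sorted(site_ts)
        for t in site_ts:
            for el in config.flank_model:
                if rng.random() < el.prob:
                    w = _realize_iupac(rng, el.pattern)
                    s = t + el.offset
                    if 0 <= s and s + len(w) <= tlen:
                        sense[s : s + len(w)] = list(w)
        core_spans = []
        for t in site_ts:
            motif = at_names[rng.choice(len(at_names), p=at_probs)]
            word = _realize_iupac(rng, motif)
            a_idx = motif.upper().replace("U", "T").index("A", 1)  # the m6A base
            start = t - a_idx
            sense[start : start + len(word)] = list(word)
            core_spans.append((start, start + len(word)))
        cl_ts = []
        for t in site_ts:
            if rng.random() >= config.crosslink_prob:
                continue
            off = int(round(rng.normal(config.crosslink_offset_mean,
                                       config.crosslink_offset_sd)))
            if -2 <= off <= 2:  # keep the crosslink off the methylated core
                off = -3 if off <= 0 else 3
            ct = min(max(t + off, 0), tlen - 1)
            while any(s <= ct < e for s, e in core_spans) and ct > 0:
                ct -= 1
            if any(s <= ct < e for s, e in core_spans):
                continue
            sense[ct] = "T"  # crosslinks happen at uridines
            cl_ts.append(ct)

        strand = "+" if rng.random() < 0.5 else "-"
        chrom_i = g % config.n_chroms
        chrom = f"chr{chrom_i + 1}"
        spacer = int(rng.integers(*config.spacer_len))
        chrom_parts[chrom_i].append(
            "".join(_draw_seq(rng, spacer, config.base_freqs).astype("U1"))
        )
        gstart = chrom_cursor[chrom_i] + spacer
        sense_str = "".join(sense)
        genomic = sense_str if strand == "+" else revcomp(sense_str)
        chrom_parts[chrom_i].append(genomic)
        chrom_cursor[chrom_i] = gstart + tlen

        def t2g(t: int) -> int:
            return gstart + t if strand == "+" else gstart + tlen - 1 - t

        if strand == "+":
            bounds = [
                (gstart, gstart + u5),
                (gstart + u5, gstart + u5 + cds),
                (gstart + u5 + cds, gstart + tlen),
            ]
        else:
            bounds = [
                (gstart + tlen - u5, gstart + tlen),
                (gstart + u3, gstart + tlen - u5),
                (gstart, gstart + u3),
            ]
        gene_rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "start": gstart,
                "end": gstart + tlen,
                "5UTR_start": bounds[0][0],
                "5UTR_end": bounds[0][1],
                "CDS_start": bounds[1][0],
                "CDS_end": bounds[1][1],
                "3UTR_start": bounds[2][0],
                "3UTR_end": bounds[2][1],
            }
        )
        for t in site_ts:
            m6a_rows.append((chrom, t2g(t), strand, 1.0, gid))
        for ct in cl_ts:
            cl_rows.append(
                (chrom, t2g(ct), strand, float(1.0 + rng.gamma(2.0, 2.0)), gid)
            )

    seqs = {f"chr{i + 1}": "".join(parts) for i, parts in enumerate(chrom_parts)}
    bundle = GenomeBundle(seqs=seqs, genes=pd.DataFrame(gene_rows))

    def _sites(rows, source):
        if not rows:
            df = make_site_table([], [], [], source=source)
        else:
            chroms, pos, strands, scores, gids = zip(*rows)
            df = make_site_table(list(chroms), list(pos), list(strands),
                                 list(scores), source)
            df["gene_id"] = gids
        return df

    m6a = _sites(m6a_rows, "m6a")
    crosslinks = _sites(cl_rows, "crosslink")
    targets = sorted(m6a["gene_id"].unique()) if len(m6a) else []

    # expression: targets and non-targets drawn from the same distribution
    tpm = pd.Series(
        np.round(rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes), 3),
        index=bundle.genes["gene_id"],
        name="tpm",
    )
    truth = {"m6a": m6a, "crosslinks": crosslinks, "targets": targets, "tpm": tpm}
    return bundle, truth


# ----------------------------------------------------------------------
# editing count tables
# ----------------------------------------------------------------------
def _beta_binomial(rng, n, p, rho):
    """Draw beta-binomial counts; degenerates to binomial for tiny rho."""
    p = np.broadcast_to(p, n.shape).astype(float)
    out = np.zeros(n.shape, dtype=int)
    pos = (n > 0) & (p > 0)
    if rho < 1e-9:
        out[pos] = rng.binomial(n[pos], p[pos])
        return out
    a = p[pos] * (1 - rho) / rho
    b = (1 - p[pos]) * (1 - rho) / rho
    pi = rng.beta(a, b)
    out[pos] = rng.binomial(n[pos], pi)
    return out


def sense_a_positions(bundle: GenomeBundle) -> pd.DataFrame:
    """All transcript positions whose sense-strand base is A."""
    frames = []
    for _, row in bundle.genes.iterrows():
        seq = np.frombuffer(
            bundle.seqs[row["chrom"]][row["start"] : row["end"]].encode(), dtype="S1"
        )
        target = b"A" if row["strand"] == "+" else b"T"
        pos = row["start"] + np.flatnonzero(seq == target)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": row["chrom"],
                    "pos0": pos,
                    "strand": row["strand"],
                    "gene_id": row["gene_id"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class EditingCounts:
    """Per-site, per-sample base counts with sample metadata.

    ``counts`` has shape (n_sites, n_samples, 4) over genomic A/C/G/T.
    ``sites`` carries chrom, pos0, strand, ref (genomic reference base).
    ``samples`` carries sample, condition (fusion/control), line, adar_tpm.
    """

    def __init__(self, sites: pd.DataFrame, samples: pd.DataFrame,
                 counts: np.ndarray):
        self.sites = sites.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self.counts = counts

    def __len__(self) -> int:
        return len(self.sites)

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.samples["condition"] == condition).to_numpy()

    def to_tsv(self, path) -> None:
        df = self.sites[["chrom", "pos0", "strand", "ref"]].copy()
        for j, s in enumerate(self.samples["sample"]):
            for k, b in enumerate(BASES):
                df[f"{s}_{b}"] = self.counts[:, j, k]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame) -> "EditingCounts":
        df = pd.read_csv(path, sep="\t")
        sites = df[["chrom", "pos0", "strand", "ref"]].copy()
        counts = np.zeros((len(df), len(samples), 4), dtype=int)
        for j, s in enumerate(samples["sample"]):
            for k, b in enumerate(BASES):
                counts[:, j, k] = df[f"{s}_{b}"]
        return cls(sites, samples, counts)


def simulate_editing_counts(
    bundle: GenomeBundle,
    truth_sites: pd.DataFrame,
    config: SimConfig,
    positions: pd.DataFrame | None = None,
) -> EditingCounts:
    """Simulate fusion/control base counts at transcript A positions.

    ``truth_sites`` marks the truly edited positions (must be sense-strand
    A); at those, fusion samples draw alternative-base counts at
    ``ep_target`` while control samples and all other positions draw at
    ``ep_background``, both with beta-binomial noise.  SNP artifacts are
    planted at editing proportion ~1 in a single line group.  Only rows
    with at least one mismatch in at least one sample are returned,
    mirroring a pileup of positions mismatching the reference.

    ``positions`` optionally restricts the simulated panel (a DataFrame
    with chrom/pos0/strand); the default is every sense-A transcript
    position in the genome.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    if positions is None:
        positions = sense_a_positions(bundle)
    sites = positions[["chrom", "pos0", "strand"]].reset_index(drop=True).copy()
    n_sites = len(sites)
    sites["ref"] = np.where(sites["strand"] == "+", "A", "T")

    key = pd.MultiIndex.from_frame(sites[["chrom", "pos0", "strand"]])
    true_key = pd.MultiIndex.from_frame(
        truth_sites[["chrom", "pos0", "strand"]]
    ) if len(truth_sites) else pd.MultiIndex.from_arrays([[], [], []])
    is_true = key.isin(true_key)

    samples = pd.DataFrame(
        {
            "sample": [f"F{i + 1}" for i in range(config.n_fusion)]
            + [f"C{i + 1}" for i in range(config.n_control)],
            "condition": ["fusion"] * config.n_fusion
            + ["control"] * config.n_control,
            "line": [f"LF{i + 1}" for i in range(config.n_fusion)]
            + [f"LC{i + 1}" for i in range(config.n_control)],
            "adar_tpm": np.round(
                rng.uniform(20, 60, size=config.n_fusion + config.n_control), 2
            ),
        }
    )
    n_samp = len(samples)
    fusion = (samples["condition"] == "fusion").to_numpy()

    p = np.full((n_sites, n_samp), config.ep_background)
    p[np.ix_(is_true, fusion)] = config.ep_target

    # line-group SNP artifacts: editing proportion ~1 in one group only
    n_snp = int(round(config.snp_fraction * max(int(is_true.sum()), 1)))
    snp_pool = np.flatnonzero(~is_true)
    snp_idx = rng.choice(snp_pool, size=min(n_snp, snp_pool.size), replace=False)
    snp_group_fusion = rng.random(snp_idx.size) < 0.5
    for i, idx in enumerate(snp_idx):
        grp = fusion if snp_group_fusion[i] else ~fusion
        p[idx, grp] = rng.uniform(0.95, 1.0)

    coverage = rng.poisson(config.coverage_mean, size=(n_sites, n_samp))
    alt = _beta_binomial(rng, coverage, p, config.bb_overdispersion)
    # sparse sequencing noise at a base that is neither the reference nor
    # the deamination product, so it only ever creates non-A-to-G mismatches
    other = rng.binomial(coverage, 0.002)

    counts = np.zeros((n_sites, n_samp, 4), dtype=int)
    plus = sites["strand"].to_numpy() == "+"
    ref_idx = np.where(plus, 0, 3)
    alt_idx = np.where(plus, 2, 1)  # G / C
    bit = rng.integers(0, 2, size=(n_sites, n_samp))
    # plus strand: C or T; minus strand: A or G
    other_choices = np.where(plus[:, None], 1 + 2 * bit, 2 * bit)
    rows = np.arange(n_sites)[:, None]
    cols = np.arange(n_samp)[None, :]
    counts[rows, cols, ref_idx[:, None]] = coverage - alt
    counts[rows, cols, alt_idx[:, None]] += alt
    np.add.at(counts, (rows + 0 * other_choices, cols + 0 * other_choices,
                       other_choices), other)
    counts[rows, cols, ref_idx[:, None]] -= np.minimum(
        other, counts[rows, cols, ref_idx[:, None]]
    )

    mismatch = counts.sum(axis=(1, 2)) - counts[rows[:, 0], :, ref_idx].sum(axis=1)
    keep = mismatch > 0
    sites["is_snp_artifact"] = False
    sites.loc[snp_idx, "is_snp_artifact"] = True
    ec = EditingCounts(sites[keep].reset_index(drop=True), samples, counts[keep])
    logger.info(
        "simulated %d/%d positions with >=1 mismatch (%d true, %d SNP artifacts)",
        keep.sum(), n_sites, is_true.sum(), snp_idx.size,
    )
    return ec


def simulate_single_cell(
    bundle: GenomeBundle,
    targets: list[str],
    config: SimConfig,
    reader_gene: str = "READER",
) -> pd.DataFrame:
    """Binary genes x cells expression matrix with reader/target coupling.

    Target genes are expressed preferentially in reader-expressing cells
    (per-gene coexpression strength drawn uniformly), so the coexpression
    statistic has signal to find.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = list(bundle.genes["gene_id"])
    reader = rng.random(config.n_cells) < config.reader_cell_fraction
    mat = np.zeros((len(genes) + 1, config.n_cells), dtype=int)
    mat[0] = reader.astype(int)
    target_set = set(targets)
    for i, g in enumerate(genes, start=1):
        base = rng.uniform(0.05, 0.4)
        if g in target_set:
            boost = rng.uniform(1.5, 4.0)
            pr = np.where(reader, min(base * boost, 0.95), base)
        else:
            pr = np.full(config.n_cells, base)
        mat[i] = (rng.random(config.n_cells) < pr).astype(int)
    return pd.DataFrame(
        mat, index=[reader_gene] + genes,
        columns=[f"cell{j}" for j in range(config.n_cells)],
    )


def write_truth_manifest(truth: dict, path) -> None:
    manifest = {
        "n_m6a_sites": int(len(truth["m6a"])),
        "n_crosslink_sites": int(len(truth["crosslinks"])),
        "n_target_genes": int(len(truth["targets"])),
        "targets": list(truth["targets"]),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
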