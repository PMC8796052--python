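"""Genome and annotation containers shared by the whole pipeline.

A :class:`GenomeBundle` holds chromosome sequences together with a
single-transcript-per-gene annotation in which every gene is a contiguous
5'UTR -> CDS -> 3'UTR block on a declared strand.  It provides the interval
lookups the downstream modules need: assigning single-nucleotide sites to
genes (ties broken by expression), locating a position within a gene-body
feature, binning relative positions, and sampling random transcript
positions for background sets.

Coordinates are 0-based half-open everywhere in memory.  Sequences are
stored in the DNA alphabet (ACGT); modules that report nucleotide
identities to the user translate T to U at the boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger("tribeclip")

FEATURES = ("5UTR", "CDS", "3UTR")
#: GFF3 type names for the three gene-body features, in transcript order.
GFF_TYPES = {"5UTR": "five_prime_UTR", "CDS": "CDS", "3UTR": "three_prime_UTR"}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Report a sense-strand DNA string in the RNA alphabet."""
    return seq.replace("T", "U").replace("t", "u")


@dataclass
class GenomeBundle:
    """Chromosome sequences plus contiguous single-transcript gene models.

    Parameters
    ----------
    seqs
        Mapping of chromosome name to sequence (DNA alphabet, plus strand).
    genes
        One row per gene with columns ``gene_id, chrom, strand, start, end``
        and genomic half-open intervals ``{5UTR,CDS,3UTR}_{start,end}``.
        For minus-strand genes the 5'UTR occupies the high-coordinate end.
    """

    seqs: dict[str, str]
    genes: pd.DataFrame
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _merged: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)

    # ------------------------------------------------------------------
    # interval indexes
    # ------------------------------------------------------------------
    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            tree = IntervalTree()
            sub = self.genes[self.genes["chrom"] == chrom]
            for idx, row in sub.iterrows():
                tree[row["start"] : row["end"]] = idx
            self._trees[chrom] = tree
        return self._trees[chrom]

    def merged_gene_intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Strand-agnostic union of gene spans, as sorted (starts, ends)."""
        if chrom not in self._merged:
            sub = self.genes[self.genes["chrom"] == chrom].sort_values("start")
            starts, ends = [], []
            for s, e in zip(sub["start"], sub["end"]):
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[chrom] = (np.asarray(starts), np.asarray(ends))
        return self._merged[chrom]

    def overlaps_gene(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorized: does each (chrom, pos) fall inside any annotated gene?"""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        for c in np.unique(chrom):
            starts, ends = self.merged_gene_intervals(c)
            m = chrom == c
            if starts.size == 0:
                continue
            idx = np.searchsorted(starts, pos[m], side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[m][ok] < ends[idx[ok]]
            out[m] = ok
        return out

    # ------------------------------------------------------------------
    # per-position annotation
    # ------------------------------------------------------------------
    def feature_at(self, gene_idx: int, pos: int) -> tuple[str, float]:
        """Feature and relative position (transcript-oriented, in [0, 1))."""
        row = self.genes.loc[gene_idx]
        for feat in FEATURES:
            fs, fe = row[f"{feat}_start"], row[f"{feat}_end"]
            if fs <= pos < fe:
                if row["strand"] == "+":
                    rel = (pos - fs) / (fe - fs)
                else:
                    rel = (fe - 1 - pos) / (fe - fs)
                return feat, rel
        return "intergenic", np.nan

    def _has_overlapping_genes(self) -> bool:
        for chrom in self.genes["chrom"].unique():
            sub = self.genes[self.genes["chrom"] == chrom].sort_values("start")
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                return True
        return False

    def _feature_arrays(self):
        """Per-gene bound arrays for vectorized feature lookup."""
        g = self.genes
        return {
            feat: (
                g[f"{feat}_start"].to_numpy(),
                g[f"{feat}_end"].to_numpy(),
            )
            for feat in FEATURES
        }

    def _assign_fast(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Vectorized gene assignment for non-overlapping annotations."""
        gidx_out = np.full(len(sites), -1)
        pos_all = sites["pos0"].to_numpy()
        chrom_all = sites["chrom"].to_numpy()
        for chrom in np.unique(chrom_all):
            sub = self.genes[self.genes["chrom"] == chrom].sort_values("start")
            if len(sub) == 0:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            m = chrom_all == chrom
            cand = np.searchsorted(starts, pos_all[m], side="right") - 1
            ok = cand >= 0
            ok[ok] &= pos_all[m][ok] < ends[cand[ok]]
            res = np.full(m.sum(), -1)
            res[ok] = sub.index.to_numpy()[cand[ok]]
            gidx_out[m] = res
        out = sites.copy()
        hit = gidx_out >= 0
        gi = np.where(hit, gidx_out, 0)
        feats = np.full(len(sites), "intergenic", dtype=object)
        rels = np.full(len(sites), np.nan)
        strands = self.genes["strand"].to_numpy()[gi]
        for feat, (fs, fe) in self._feature_arrays().items():
            s, e = fs[gi], fe[gi]
            inside = hit & (pos_all >= s) & (pos_all < e)
            feats[inside] = feat
            fwd = (pos_all - s) / (e - s)
            rev = (e - 1 - pos_all) / (e - s)
            rels[inside] = np.where(strands[inside] == "+", fwd[inside],
                                    rev[inside])
        out["gene_id"] = np.where(
            hit, self.genes["gene_id"].to_numpy()[gi], None
        )
        out["feature"] = feats
        out["rel_pos"] = rels
        return out

    def assign_genes(
        self, sites: pd.DataFrame, tpm: pd.Series | None = None
    ) -> pd.DataFrame:
        """Assign each site to a gene, with feature and relative position.

        Overlapping-gene ties are broken by higher expression (``tpm``,
        missing genes count as 0) and then lexicographic gene id.  Sites
        inside a gene on the same strand are preferred over opposite-strand
        overlaps; sites outside every gene get feature ``intergenic``.
        With a non-overlapping annotation the assignment is unique and a
        vectorized fast path is used.
        """
        if len(sites) and not self._has_overlapping_genes():
            return self._assign_fast(sites.reset_index(drop=True))
        tpm = tpm if tpm is not None else pd.Series(dtype=float)
        genes, feats, rels = [], [], []
        for chrom, pos, strand in zip(
            sites["chrom"], sites["pos0"], sites.get("strand", [None] * len(sites))
        ):
            hits = sorted(self._tree(chrom)[pos], key=lambda iv: iv.data)
            idxs = [iv.data for iv in hits]
            if strand is not None and idxs:
                same = [i for i in idxs if self.genes.loc[i, "strand"] == strand]
                if same:
                    idxs = same
            if not idxs:
                genes.append(None)
                feats.append("intergenic")
                rels.append(np.nan)
                continue
            best = min(
                idxs,
                key=lambda i: (
                    -float(tpm.get(self.genes.loc[i, "gene_id"], 0.0)),
                    self.genes.loc[i, "gene_id"],
                ),
            )
            feat, rel = self.feature_at(best, pos)
            genes.append(self.genes.loc[best, "gene_id"])
            feats.append(feat)
            rels.append(rel)
        out = sites.copy()
        out["gene_id"] = genes
        out["feature"] = feats
        out["rel_pos"] = rels
        return out

    # ------------------------------------------------------------------
    # sequence access
    # ------------------------------------------------------------------
    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.seqs[chrom][max(start, 0) : end]
        return revcomp(seq) if strand == "-" else seq

    def contig_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    # ------------------------------------------------------------------
    # transcript-position enumeration and sampling
    # ------------------------------------------------------------------
    def transcript_positions(self, gene_ids=None) -> pd.DataFrame:
        """Enumerate every transcript nucleotide with feature and rel_pos.

        Heavy for large genomes; intended for the desk-scale synthetic
        genomes this package simulates.
        """
        sub = self.genes
        if gene_ids is not None:
            keep = set(gene_ids)
            sub = sub[sub["gene_id"].isin(keep)]
        frames = []
        for _, row in sub.iterrows():
            for feat in FEATURES:
                fs, fe = row[f"{feat}_start"], row[f"{feat}_end"]
                pos = np.arange(fs, fe)
                if row["strand"] == "+":
                    rel = (pos - fs) / (fe - fs)
                else:
                    rel = (fe - 1 - pos) / (fe - fs)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": row["chrom"],
                            "pos0": pos,
                            "strand": row["strand"],
                            "gene_id": row["gene_id"],
                            "feature": feat,
                            "rel_pos": rel,
                        }
                    )
                )
        if not frames:
            return pd.DataFrame(
                columns=["chrom", "pos0", "strand", "gene_id", "feature", "rel_pos"]
            )
        return pd.concat(frames, ignore_index=True)

    def random_transcript_positions(
        self, n: int, rng: np.random.Generator
    ) -> pd.DataFrame:
        """Sample ``n`` positions uniformly over all transcript nucleotides."""
        lengths = (self.genes["end"] - self.genes["start"]).to_numpy()
        gidx = rng.choice(len(self.genes), size=n, p=lengths / lengths.sum())
        offset = rng.integers(0, lengths[gidx])
        rows = self.genes.iloc[gidx].reset_index(drop=True)
        pos = rows["start"].to_numpy() + offset
        strands = rows["strand"].to_numpy()
        feats = np.full(n, "intergenic", dtype=object)
        rels = np.full(n, np.nan)
        for feat, (fs, fe) in self._feature_arrays().items():
            s, e = fs[gidx], fe[gidx]
            inside = (pos >= s) & (pos < e)
            feats[inside] = feat
            fwd = (pos - s) / (e - s)
            rev = (e - 1 - pos) / (e - s)
            rels[inside] = np.where(strands[inside] == "+", fwd[inside],
                                    rev[inside])
        return pd.DataFrame(
            {
                "chrom": rows["chrom"],
                "pos0": pos,
                "strand": strands,
                "gene_id": rows["gene_id"].to_numpy(),
                "feature": feats,
                "rel_pos": rels,
            }
        )

    # ------------------------------------------------------------------
    # IO
    # ------------------------------------------------------------------
    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, row in self.genes.iterrows():
                gid = row["gene_id"]
                common = (row["chrom"], "tribeclip")
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                *common,
                                "gene",
                                row["start"] + 1,
                                row["end"],
                                ".",
                                row["strand"],
                                ".",
                                f"ID={gid}",
                            ),
                        )
                    )
                    + "\n"
                )
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                *common,
                                "mRNA",
                                row["start"] + 1,
                                row["end"],
                                ".",
                                row["strand"],
                                ".",
                                f"ID={gid}.1;Parent={gid}",
                            ),
                        )
                    )
                    + "\n"
                )
                for feat in FEATURES:
                    fh.write(
                        "\t".join(
                            map(
                                str,
                                (
                                    *common,
                                    GFF_TYPES[feat],
                                    row[f"{feat}_start"] + 1,
                                    row[f"{feat}_end"],
                                    ".",
                                    row["strand"],
                                    "0" if feat == "CDS" else ".",
                                    f"ID={gid}.1.{feat};Parent={gid}.1",
                                ),
                            )
                        )
                        + "\n"
                    )

    @classmethod
    def from_files(cls, fasta_path, gff3_path) -> "GenomeBundle":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        inv_types = {v: k for k, v in GFF_TYPES.items()}
        rows: dict[str, dict] = {}
        for gene in db.features_of_type("gene"):
            gid = gene.id
            rows[gid] = {
                "gene_id": gid,
                "chrom": gene.seqid,
                "strand": gene.strand,
                "start": gene.start - 1,
                "end": gene.end,
            }
            for child in db.children(gene):
                if child.featuretype in inv_types:
                    feat = inv_types[child.featuretype]
                    rows[gid][f"{feat}_start"] = child.start - 1
                    rows[gid][f"{feat}_end"] = child.end
        genes = pd.DataFrame(list(rows.values()))
        return cls(seqs=seqs, genes=genes)


def bin_of(rel_pos: np.ndarray, bins: int) -> np.ndarray:
    """Map relative positions in [0, 1) to integer bins 0..bins-1."""
    rel = np.asarray(rel_pos, dtype=float)
    out = np.floor(rel * bins).astype(int)
    return np.clip(out, 0, bins - 1)


# ----------------------------------------------------------------------
# site tables and BED IO
# ----------------------------------------------------------------------
SITE_COLUMNS = ["chrom", "pos0", "strand", "score", "source"]


def make_site_table(
    chrom, pos0, strand, score=0.0, source: str = ""
) -> pd.DataFrame:
    """Normalized single-nucleotide site table."""
    df = pd.DataFrame({"chrom": chrom, "pos0": pos0, "strand": strand})
    df["score"] = score
    df["source"] = source
    return df


def write_bed(sites: pd.DataFrame, path, name_col: str = "source") -> None:
    """Write single-nucleotide sites (or intervals with start/end) as BED6."""
    if {"start", "end"} <= set(sites.columns):
        start, end = sites["start"], sites["end"]
    else:
        start, end = sites["pos0"], sites["pos0"] + 1
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": start,
            "end": end,
            "name": sites.get(name_col, "."),
            "score": sites.get("score", 0.0),
            "strand": sites.get("strand", "."),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, single_nt: bool = True) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos0": df["start"],
            "strand": df["strand"],
            "score": df["score"],
            "source": df["name"],
        }
    )
    if not single_nt:
        out["start"] = df["start"]
        out["end"] = df["end"]
    return out
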