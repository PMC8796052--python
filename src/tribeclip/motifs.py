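"""Position weight matrices, genome scanning, and motif geography.

PWMs are log2-odds matrices over {A,C,G,U} against fixed background letter
frequencies (defaults A 0.273, C 0.165, G 0.173, U 0.389, a U-rich
transcriptome-like composition).  Entry (b, j) is

    PWM[b, j] = log2( p_adj(b, j) / p(b) ),
    p_adj = (p_hat(b, j) + pseudo * p(b)) / (1 + pseudo),

with a small pseudo-frequency so that unobserved bases stay finite and a
column observed exactly at background scores 0.  PWMs are seeded from
IUPAC patterns (ambiguity codes expand to uniform frequencies over the
allowed bases) or built from aligned sequence windows; scanning keeps
windows whose summed score reaches a threshold (default 4, which for short
motifs retains essentially exact matches).

The module also builds location-matched backgrounds (random sites in
non-target genes reproducing the anchors' gene-body feature/bin histogram
exactly), motif distance profiles around anchor sites (counts per 1000
anchors, with a gene-overlap eligibility rule at each shift), and
observed/expected gene-body enrichment against a large random-position
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBundle, bin_of, FEATURES
from .synthdata import IUPAC

logger = logging.getLogger("tribeclip")

#: Background letter frequencies over A, C, G, U.
DEFAULT_BACKGROUND = np.array([0.273, 0.165, 0.173, 0.389])
DEFAULT_MIN_SCORE = 4.0
RNA_BASES = "ACGU"

# The curated motif catalogue: consensus-site variants (RRACH family and
# GGAU), U/Y-rich flanking elements, and literature motifs, padded with
# systematic variants to the 48 entries the analysis expects.  This is a
# curated reconstruction of the elements recurrently reported around plant
# m6A sites and reader crosslink sites; provenance tags record the family.
_CONSENSUS = [
    "DRACH", "RRACH", "RACH", "DRAY", "URACH", "DRACG", "DGACH", "RGACH",
    "AAACH", "GGACH", "AGACH", "GAACH", "DRACA", "DRACC", "DRACU", "RRACU",
]
_GGAU_FAMILY = ["GGAU", "UGGAU", "GGAUH", "DGGAU", "GGAUU"]
_U_RICH = [
    "UUUUU", "UNUNU", "URURU", "URUAY", "YYYYY", "UUUUUU", "UYUYU",
    "YUYUY", "UUYUU", "UCUCU", "CUCUC", "UUUGU", "UGUUU",
]
_LITERATURE = [
    "YUGUM", "UGUAMM", "UGWAMH", "UGUAWA", "UGAAC", "ACUCU", "DRACUCU",
    "URUAYY", "UUGAAC", "AYUCU", "YACUCU", "UGUAY", "UGUAM", "YUGUAM",
]
MOTIF_CATALOGUE: dict[str, tuple[str, str]] = {}
for _name in _CONSENSUS:
    MOTIF_CATALOGUE[_name] = (_name, "consensus")
for _name in _GGAU_FAMILY:
    MOTIF_CATALOGUE[_name] = (_name, "ggau")
for _name in _U_RICH:
    MOTIF_CATALOGUE[_name] = (_name, "u_rich")
for _name in _LITERATURE:
    MOTIF_CATALOGUE[_name] = (_name, "literature")
assert len(MOTIF_CATALOGUE) == 48


@dataclass
class PWM:
    """Log2-odds position weight matrix (length x 4 over A,C,G,U/T)."""

    name: str
    matrix: np.ndarray  # (L, 4)
    pattern: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM entries must be finite")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def score(self, window: str) -> float:
        enc = encode(window)
        if enc.size != len(self) or (enc > 3).any():
            raise ValueError("window length/alphabet mismatch")
        return float(self.matrix[np.arange(len(self)), enc].sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.pattern,
                   self.provenance)


_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i
_ENCODE_LUT[ord("U")] = 3
_ENCODE_LUT[ord("u")] = 3


def encode(seq: str) -> np.ndarray:
    """DNA/RNA string to integer codes A=0 C=1 G=2 T/U=3 (other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def build_pwm(
    aligned_windows,
    background: np.ndarray = DEFAULT_BACKGROUND,
    pseudo: float = 1e-4,
    name: str = "",
) -> PWM:
    """PWM from equal-length aligned sequence windows."""
    windows = list(aligned_windows)
    if not windows:
        raise ValueError("need at least one window")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must have uniform length")
    counts = np.zeros((length, 4))
    for w in windows:
        enc = encode(w)
        ok = enc < 4
        counts[np.flatnonzero(ok), enc[ok]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return PWM(name, _log_odds(freqs, background, pseudo))


def _log_odds(freqs, background, pseudo):
    bg = np.asarray(background, dtype=float)
    adj = (freqs + pseudo * bg[None, :]) / (1 + pseudo)
    return np.log2(adj / bg[None, :])


def iupac_pwm(
    pattern: str,
    background: np.ndarray = DEFAULT_BACKGROUND,
    pseudo: float = 1e-4,
    name: str | None = None,
    provenance: str = "",
) -> PWM:
    """PWM seeded from an IUPAC pattern: uniform over the allowed bases."""
    freqs = np.zeros((len(pattern), 4))
    for j, code in enumerate(pattern.upper()):
        allowed = [encode(b)[0] for b in IUPAC[code]]
        freqs[j, allowed] = 1.0 / len(allowed)
    return PWM(name or pattern, _log_odds(freqs, background, pseudo),
               pattern=pattern, provenance=provenance)


def load_catalogue(
    background: np.ndarray = DEFAULT_BACKGROUND, pseudo: float = 1e-4
) -> dict[str, PWM]:
    """The packaged 48-motif catalogue as named PWMs."""
    return {
        name: iupac_pwm(pattern, background, pseudo, name=name, provenance=tag)
        for name, (pattern, tag) in MOTIF_CATALOGUE.items()
    }


def write_catalogue(path, catalogue: dict[str, tuple[str, str]] = MOTIF_CATALOGUE):
    pd.DataFrame(
        [(n, p, t) for n, (p, t) in catalogue.items()],
        columns=["name", "pattern", "provenance"],
    ).to_csv(path, sep="\t", index=False)


def read_catalogue(path) -> dict[str, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {r["name"]: (r["pattern"], r["provenance"]) for _, r in df.iterrows()}


# ----------------------------------------------------------------------
# scanning
# ----------------------------------------------------------------------
def _strand_scores(enc: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    length = matrix.shape[0]
    n = enc.size
    if n < length:
        return np.empty(0)
    scores = np.zeros(n - length + 1)
    for j in range(length):
        col = np.append(matrix[j], -np.inf)  # index 4 = unknown base
        scores += col[enc[j : j + n - length + 1]]
    return scores


def scan_genome(
    pwm: PWM,
    sequences: dict[str, str],
    min_score: float = DEFAULT_MIN_SCORE,
) -> pd.DataFrame:
    """Scan both strands of every sequence for PWM matches >= min_score.

    Returns chrom, start (0-based), end, strand, score, motif.  Equivalent
    to exhaustive window enumeration.
    """
    length = len(pwm)
    rows = []
    for chrom, seq in sequences.items():
        if len(seq) < length:
            logger.info("scan_genome: %s shorter than motif %s", chrom, pwm.name)
            continue
        enc = encode(seq)
        fwd = _strand_scores(enc, pwm.matrix)
        hits = np.flatnonzero(fwd >= min_score)
        for i in hits:
            rows.append((chrom, int(i), int(i + length), "+", float(fwd[i])))
        rc = np.where(enc == 4, 4, 3 - enc)[::-1]
        rev = _strand_scores(rc, pwm.matrix)
        hits = np.flatnonzero(rev >= min_score)
        n = enc.size
        for i in hits:
            start = n - length - int(i)
            rows.append((chrom, start, start + length, "-", float(rev[i])))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])
    out["motif"] = pwm.name
    return out.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def scan_catalogue(
    catalogue: dict[str, PWM],
    sequences: dict[str, str],
    min_score: float = DEFAULT_MIN_SCORE,
) -> pd.DataFrame:
    frames = [scan_genome(p, sequences, min_score) for p in catalogue.values()]
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# matched background
# ----------------------------------------------------------------------
def matched_background(
    sites: pd.DataFrame,
    bundle: GenomeBundle,
    non_target_genes,
    bins_per_feature: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Location-matched background sites in non-target genes.

    For every anchor, one background site is drawn in a non-target gene at
    the same gene-body feature and relative-position bin (``bins_per_feature``
    bins per feature), so the joint (feature, bin) histogram of the
    background equals that of the anchors exactly.  Raises if a stratum has
    no available non-target positions.
    """
    if "feature" not in sites.columns:
        raise ValueError("sites must be annotated (feature, rel_pos)")
    pool = bundle.transcript_positions(gene_ids=non_target_genes)
    if len(pool) == 0:
        raise ValueError("no non-target positions available")
    pool = pool.copy()
    pool["bin"] = bin_of(pool["rel_pos"].to_numpy(), bins_per_feature)
    grouped = {k: v for k, v in pool.groupby(["feature", "bin"])}

    rng = np.random.default_rng(seed)
    anchors = sites[sites["feature"].isin(FEATURES)].copy()
    anchors["bin"] = bin_of(anchors["rel_pos"].to_numpy(), bins_per_feature)
    out = []
    for (feat, b), grp in anchors.groupby(["feature", "bin"]):
        cand = grouped.get((feat, b))
        if cand is None or len(cand) == 0:
            raise ValueError(
                f"no non-target background positions in stratum ({feat}, bin {b})"
            )
        k = len(grp)
        replace = k > len(cand)
        take = cand.iloc[rng.choice(len(cand), size=k, replace=replace)]
        out.append(take)
    bg = pd.concat(out, ignore_index=True)
    bg["source"] = "matched_background"
    bg["score"] = 0.0
    return bg


# ----------------------------------------------------------------------
# distance profiles
# ----------------------------------------------------------------------
class _MatchIndex:
    """Point-overlap queries against fixed-length match intervals."""

    def __init__(self, matches: pd.DataFrame):
        self.length = int((matches["end"] - matches["start"]).max()) if len(
            matches
        ) else 0
        self.starts = {
            key: np.sort(grp["start"].to_numpy())
            for key, grp in matches.groupby(["chrom", "strand"])
        }

    def overlaps(self, chrom: str, strand: str, pos: np.ndarray) -> np.ndarray:
        starts = self.starts.get((chrom, strand))
        if starts is None or self.length == 0:
            return np.zeros(pos.shape, dtype=bool)
        hi = np.searchsorted(starts, pos, side="right")
        lo = np.searchsorted(starts, pos - self.length, side="right")
        return hi > lo


def _profile(
    matches_index: _MatchIndex,
    anchors: pd.DataFrame,
    bundle: GenomeBundle,
    half_window: int,
) -> pd.DataFrame:
    offsets = np.arange(-half_window, half_window + 1)
    hit = np.zeros(offsets.size)
    eligible = np.zeros(offsets.size)
    for (chrom, strand), grp in anchors.groupby(["chrom", "strand"]):
        pos = grp["pos0"].to_numpy()
        sign = 1 if strand == "+" else -1
        for k, d in enumerate(offsets):
            shifted = pos + sign * d
            ok = bundle.overlaps_gene(np.repeat(chrom, shifted.size), shifted)
            eligible[k] += ok.sum()
            if ok.any():
                hv = matches_index.overlaps(chrom, strand, shifted[ok])
                hit[k] += hv.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        per1000 = np.where(eligible > 0, 1000.0 * hit / np.maximum(eligible, 1),
                           np.nan)
    return pd.DataFrame(
        {"offset": offsets, "per_1000": per1000, "n_eligible": eligible.astype(int)}
    )


def motif_distance_profile(
    matches: pd.DataFrame,
    anchors: pd.DataFrame,
    bundle: GenomeBundle,
    background: pd.DataFrame | None = None,
    half_window: int = 50,
) -> pd.DataFrame:
    """Motif occurrences per 1000 anchors at each signed offset.

    Offsets are strand-oriented (negative = 5' on the anchor's transcript
    strand); an anchor contributes at offset d if the shifted position still
    overlaps an annotated gene (eligibility denominator) and counts as a
    hit if it overlaps a motif match at any point.  If ``background``
    anchors are given, their profile is returned alongside.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor table")
    index = _MatchIndex(matches)
    obs = _profile(index, anchors, bundle, half_window)
    if background is not None:
        bg = _profile(index, background, bundle, half_window)
        obs["background_per_1000"] = bg["per_1000"]
        obs["background_n_eligible"] = bg["n_eligible"]
    return obs


def genebody_enrichment(
    matches: pd.DataFrame,
    bundle: GenomeBundle,
    n_background: int = 1_000_000,
    bins_per_feature: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed/expected motif density per gene-body bin.

    Observed: match centers annotated to (feature, bin) in their sense
    gene.  Expected: a seeded random background of ``n_background``
    transcript positions annotated the same way.  An enrichment of 1 means
    the motif is neither over- nor under-represented at that location.
    """
    if len(bundle.genes) == 0:
        raise ValueError("empty annotation")
    if n_background < 100 * 3 * bins_per_feature:
        raise ValueError("n_background too small for stable expected bins")
    centers = pd.DataFrame(
        {
            "chrom": matches["chrom"],
            "pos0": (matches["start"] + matches["end"]) // 2,
            "strand": matches["strand"],
        }
    )
    ann = bundle.assign_genes(centers)
    # keep sense matches inside gene bodies
    ann = ann[ann["feature"].isin(FEATURES)]
    index = pd.MultiIndex.from_product(
        [FEATURES, range(bins_per_feature)], names=["feature", "bin"]
    )
    rng = np.random.default_rng(seed)
    bg = bundle.random_transcript_positions(n_background, rng)

    def hist(df):
        key = pd.MultiIndex.from_arrays(
            [df["feature"], bin_of(df["rel_pos"].to_numpy(), bins_per_feature)]
        )
        return key.value_counts().reindex(index, fill_value=0).astype(float)

    o = hist(ann)
    e = hist(bg)
    oe = (o / max(o.sum(), 1)) / (e / e.sum()).replace(0, np.nan)
    out = pd.DataFrame({"observed": o, "expected": e, "enrichment": oe})
    return out.reset_index()


def split_anchor_profiles(
    anchors: pd.DataFrame,
    target_genes,
    crosslinks: pd.DataFrame,
    matches: pd.DataFrame,
    bundle: GenomeBundle,
    near_dist: int = 25,
    half_window: int = 50,
) -> dict[str, pd.DataFrame]:
    """Distance profiles per anchor stratum.

    Anchors (m6A sites with gene assignments) are split three ways: on a
    non-target gene; on a target gene with a crosslink site within
    ``near_dist`` nt (near); on a target gene with none (far).  Empty
    strata are omitted with a log message.
    """
    from .clip import _nearest_distance

    if "gene_id" not in anchors.columns:
        raise ValueError("anchors must carry gene assignments")
    anchors = anchors.reset_index(drop=True)
    targets = set(target_genes)
    on_target = anchors["gene_id"].isin(targets).to_numpy()
    dist = _nearest_distance(anchors, crosslinks)
    strata = {
        "non_target": ~on_target,
        "target_near": on_target & (dist <= near_dist),
        "target_far": on_target & (dist > near_dist),
    }
    out = {}
    for name, mask in strata.items():
        if not mask.any():
            logger.info("split_anchor_profiles: stratum %s empty, omitted", name)
            continue
        out[name] = motif_distance_profile(
            matches, anchors[mask], bundle, half_window=half_window
        )
    return out
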