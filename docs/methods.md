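# Methods

This note documents the models, defaults, and numerical choices behind
`tribeclip`, and what the synthetic-data generator does and does not
emulate.

## Synthetic data generator (`synthdata`)

The generator produces the complete input universe of the analysis from a
single seed: genome FASTA, GFF3 annotation, truth site tables (BED),
per-sample base-count tables (TSV), per-gene TPM, and a binary single-cell
matrix. All randomness flows through named `numpy.random.default_rng`
streams derived from `SimConfig.seed` (`[seed, 0]` genome, `[seed, 1]`
counts, `[seed, 2]` single cell), so outputs are bit-reproducible.

**Genome and annotation.** Each gene is one unspliced transcript —
contiguous 5'UTR → CDS → 3'UTR — on a strand drawn 50/50, packed onto two
chromosomes with random intergenic spacers. One transcript per gene keeps
isoform selection (done by expression in real pipelines) out of scope.
Defaults: 200 genes; 5'UTR 50–150 nt, CDS 300–900 nt, 3'UTR 150–400 nt,
spacers 100–400 nt; base composition A 0.273, C 0.165, G 0.173, U 0.389 —
the U-rich composition typical of a plant transcriptome, used genome-wide
so that motif backgrounds are realistic.

**Methylation sites.** A fraction of genes (default 0.3, matching the
roughly one quarter of expressed genes that proximity labeling typically
flags as reader targets) receives Poisson(3) m6A sites in its 3'UTR —
about the empirical 3 edit sites per target gene. Each site is the A of a
realized DRACH (80%) or GGAU (20%) island; flanking elements are planted
at fixed transcript-strand offsets from the site: UNUNU starting at −15
(p = 0.8), UUUUU at −25 (p = 0.5), URUAY at −21 (p = 0.3), YYYYY at +8
(p = 0.8). Offsets are motif *starts*; a planted 5-mer at −15 occupies
offsets −15…−11. Sites within one gene are separated by more than the
motif-plan margin so neighboring plans never overwrite one another
(flanks are written first, at-site cores second, so cores always win any
residual overlap). Configurations whose 3'UTR length bounds cannot fit the
plan are rejected.

**Crosslink sites.** With probability 0.8 a site gets a crosslink at a
signed offset drawn from N(−11, 4) nt (negative = 5', matching the
observed upstream displacement of reader crosslinks from m6A), pushed out
of the ±2 nt methylated core, planted on a uridine (the photoreactive
base), with a caller-style positive score.

**Editing counts.** At every sense-strand A of every transcript (or a
caller-supplied panel), per-sample coverage is Poisson(50). Alternative
counts (G genomically on plus-strand genes, C on minus) are beta-binomial:
true sites at `ep_target` (default 0.25) in the five fusion samples,
everything else at `ep_background` (default 0.01), overdispersion rho
0.01. Genome-scale reader-HyperTRIBE datasets show generally low editing
proportions; these defaults put the bulk of true-site EPs around 0.25
with background an order of magnitude lower. The beta-binomial is this package's choice of
noise model — no generative model is prescribed by the experiments it
emulates. SNP-like artifacts (5% of the true-site count) get EP ~
Uniform(0.95, 1) in one entire line group, emulating line-specific
homozygous variants. A 0.2% per-read error channel deposits counts on a
base that is neither the reference nor the deamination product, providing
the non-A-to-G mismatches the first post-filter must remove. Only rows
with at least one mismatching read are emitted, mirroring a pileup of
mismatch positions.

**Single-cell matrix.** Binary genes × cells (500 cells); the reader is
expressed in 40% of cells and target genes are boosted in reader-positive
cells, giving the coexpression statistic signal to detect.

**What it does not emulate.** Read-level artifacts (mapping error,
strand bleed-through, PCR duplicates), splicing and isoform structure,
overlapping genes, expression-dependent coverage, and correlated editing
along a transcript. Passing tests therefore demonstrate correctness of
the statistics under the stated model, not robustness to alignment-level
pathologies of real libraries.

## Differential editing (`editing`)

Editing proportion is alt/(alt+ref) — G/(A+G) on the plus strand,
C/(T+C) on the minus strand — and 0 at zero coverage. Sites without a
putative edit (alt ≥ 1) in at least 4 of 5 fusion replicates are not
tested.

**Test statistic.** A beta-binomial *score* test: the difference of
condition rates over its null standard error, with per-site
overdispersion rho estimated by the method of moments from
within-condition residual variance and floored at the pooled across-site
estimate (per-site estimates from ten samples are noisy and truncate at
zero). A likelihood-ratio variant was evaluated first and rejected: exact
enumeration at these counts (coverage 50, background rate 0.01, 5+5
replicates) shows the signed-root LRT rejects 8.4% at nominal 5%, while
the score test rejects 4.9%; simulation confirms 4–6% across seeds.
P-values are one-sided (fusion > control) and BH-adjusted across all
tested sites.

**Calls and filters.** Significance is padj < 0.01 and log2FC > 1, with
log2FC = log2((EP_f + ε)/(EP_c + ε)), ε = 10⁻³ (the pseudocount is this
package's choice). Post-filters: (1) the dominant mismatch must be A→G
on plus / T→C on minus; (2) EP ≥ 0.9 in either condition marks a likely
SNP ("at or close to 1"; threshold exposed); (3) summed fusion coverage
must be ≥ 10 reads. Gene annotation prefers the overlapping gene with the
highest TPM, then lexicographic gene id for determinism; sites outside
genes are kept as `intergenic` but excluded from metagene statistics.

Diagnostics: a 4×(2·flank+1) nucleotide-frequency matrix at edit sites
(center all-A after strand flip), PCA of raw per-sample EPs at
significant sites, per-site Pearson correlation of EP with ADAR TPM with
a seeded scrambled-TPM background, and the coexpression statistic
(# cells expressing reader AND target) / (# cells expressing target)
with "expressing" = count > 0 (configurable).

## Crosslink-site post-processing (`clip`)

Directly adjacent peaks (consecutive genomic positions, same strand)
collapse to the highest-scoring one; score ties go to the 5'-most
position (lowest coordinate on plus, highest on minus) — the tie rule is
this package's determinism choice. Collapse is idempotent. A collapsed
crosslink site (CSS) is the dominant peak ±4 nt (9 nt), clipped and
flagged at contig edges. Full-length-protein sites split into
IDR-independent (a truncated-library site within ≤ 10 nt, unsigned, same
chromosome and strand) and IDR-dependent (none); the partition is
exhaustive. Unsigned distances are used for all nearest-neighbor
operations (the 10 nt and 25 nt rules); signed strand-oriented offsets
are used for motif profiles. Nucleotide proportions are strand-corrected
and reported over {A,C,G,U}. The metagene profile is observed/expected
per (feature, bin) against a seeded uniform-transcript-position
background.

## Motif analysis (`motifs`)

PWMs are log2-odds over {A,C,G,U} with background A 0.273, C 0.165,
G 0.173, U 0.389 and a small pseudo-frequency
(p_adj = (p̂ + pseudo·p_b)/(1+pseudo), pseudo 10⁻⁴), so a column observed
exactly at background scores 0 and entries stay finite. IUPAC patterns
seed PWMs as uniform frequencies over allowed bases; `build_pwm` derives
them from aligned windows (e.g. CSS sequences) when local refinement is
wanted — the refinement window is a configuration knob, since no single
choice is canonical. The packaged catalogue holds 48 motifs: consensus
RRACH-family variants, the GGAU family, U/Y-rich elements, and
literature motifs, padded with systematic variants; it is a curated
reconstruction (the original curated list is not fully public) and is
tagged by family.

Scanning keeps windows with summed log-odds ≥ 4 on either strand,
equivalent to exhaustive enumeration (property-tested against it). For
short motifs this threshold retains essentially exact matches, which is
why no p-value calibration machinery is attached. Note that for highly
degenerate patterns (UNUNU, YYYYY) some exact pattern realizations score
below 4 under the uniform-IUPAC PWM; planted-signal recoveries in the
tests account for this partial detection.

The matched background draws, per anchor, one random position in a
non-target gene from the same (feature, 10-bin relative position)
stratum — the joint histogram is preserved exactly, and an unfillable
stratum is an error. Distance profiles count, at each signed
strand-oriented offset d ∈ [−w, w], the anchors whose shifted position
overlaps a motif match at any point, × 1000 / (anchors still inside any
annotated gene at that shift) — the gene-overlap rule prevents 3'UTR
ends from deflating distal offsets. Because overlap is "at any point", a
planted L-mer produces an L-offset plateau; the peak is read as the
plateau. Gene-body enrichment is observed/expected per (feature, bin)
with the expectation from 10⁶ seeded random transcript positions
(desk-scaled from the 10⁷ used at genome scale; the estimator is
consistent, and the tests verify the scaled version is calibrated to
±10%). Anchor stratification splits m6A sites into non-target /
target-near / target-far with near = crosslink within 25 nt.

## Classification (`classify`)

Windows are 'at' = [−10, +10], 'up' = [−60, −11], 'down' = [+11, +60]
in transcript-strand offsets (up = 5', negative), a 21-nt core with
adjacent 50-nt flanks (121 nt total). Features are per-(motif, window)
match counts, overlap-at-any-point, truncated at 10, then standardized
(mean 0, SD 1) with statistics fitted on training rows only —
standardization is monotone, so it is harmless for trees and mainly
serves interoperability. Anchors are deduplicated greedily (keep highest
score, drop others within 120 nt) before feature building; a stratified
fifth of rows is held out.

The learner is LightGBM — the standard modern gradient-boosting
implementation — with the classical gbm parameterization: learning rate
(shrinkage) 0.05, max_depth 6 (num_leaves 2⁶), up to 2000 rounds, and
5-fold stratified CV selecting the round count that minimizes CV
binomial deviance (early stopping at 100 stagnant rounds only shortens
the search past the minimum). Runs are seeded and deterministic
(`deterministic=True`, `force_row_wise=True`). Importances are total
gain per feature normalized to sum 100. AUC is computed by the
Mann–Whitney rank statistic (tested against brute-force pair
enumeration). The reduced model refits on the top-k (default 10)
importance features and evaluates on the same held-out rows. The
bound-vs-unbound contrast labels m6A sites by crosslink proximity
(≤ 10 nt positive).

## Target comparison (`compare`)

Overlap tables enumerate every membership pattern over a gene universe
(complement included); a gene outside the universe is an error.
Expression bins: genes with TPM > 0 are ordered by log2(TPM+1) with ties
broken by stable gene-id order and cut into nine equal-frequency bins —
rank-based, hence invariant under monotone relabeling; an all-equal
table is degenerate and rejected. Per-bin target proportion is
|set ∩ bin|/|bin|; the support split partitions a target set by
membership in the union of support sets and reports per-bin
distributions of both parts.

## Problem sizes and tolerances

The test suite and the acceptance script run the pipeline at desk scale:
60–800-gene genomes for editing statistics (1,000-site null panels;
500 true + 5,000 null recovery panels), 300 genes for profile recovery,
a 6,000-gene genome for the 2,000 + 2,000 classification problem, and
10⁶-position gene-body backgrounds. Statistical assertions use either
exact equality (scanner vs enumeration, background histograms, AUC vs
pair enumeration) or sampling-error-scaled bounds (binomial 99% CI for
type-I error; 4×SD flatness for background profiles; ±10% gene-body
bins at 10⁶ background positions).

## Known limitations

* The differential test assumes independent samples and a common
  per-site overdispersion; shared-line structure across tissues is not
  modeled.
* The uniform-IUPAC PWM seeding understates the information content of
  motifs whose real position frequencies are sharper than their
  ambiguity codes; supplying CSS-derived windows to `build_pwm` is the
  intended refinement path.
* Gene assignment with overlapping genes falls back to a slower
  tie-breaking path; the generator itself never emits overlaps.
* `distance_to_nearest` and the IDR split use unsigned distances; a
  signed variant would distinguish 5' from 3' support but has no
  experimental counterpart here.
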