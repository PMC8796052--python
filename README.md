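# tribeclip

Target identification and motif geography for m6A reader proteins, from
HyperTRIBE editing data and iCLIP crosslink data.

## The problem

N6-methyladenosine (m6A) is the most abundant internal mRNA modification.
YTH-domain "reader" proteins bind methylated transcripts and steer their
fate; knowing *which* transcripts a reader binds, and *what sequence
context* surrounds its binding sites, is the central question in studies of
m6A-based regulation. Two orthogonal experimental strategies answer it:

* **HyperTRIBE** — the reader is fused to a hyperactive ADAR catalytic
  domain, which deposits A-to-I edits (read as A→G after sequencing) on
  bound transcripts. Targets are transcripts with sites edited
  significantly above a free-ADAR control.
* **iCLIP** — UV crosslinking plus immunoprecipitation maps direct
  protein-RNA contacts at single-nucleotide resolution.

`tribeclip` implements the computational side of this joint analysis as a
reusable, fully tested Python library: differential-editing calling with
the field's replicate and artifact filters, crosslink-site
post-processing, position-weight-matrix motif scanning with
location-matched backgrounds, motif distance profiles and gene-body
enrichment, gradient-boosted motif-window classification, and cross-method
target comparison. A seeded synthetic-data generator reproduces the
statistical structure of the real data (editing proportions, planted
DRACH/GGAU islands in U/Y-rich 3'UTR contexts, crosslinks displaced 5' of
m6A), so every stage is testable without any sequencing downloads.

## The statistics at the core

**Differential editing.** At a candidate site with per-sample alternative
and reference counts, editing proportions are EP = G/(A+G) on the plus
strand (C/(T+C) on the minus strand). Fusion and control conditions are
compared with a beta-binomial score test: with pooled rate p̂ and
method-of-moments overdispersion ρ,

    z = (EP_fusion − EP_control) / SE₀,
    Var(k_i) = n_i p̂ (1−p̂) (1 + (n_i − 1) ρ),

one-sided for excess editing in the fusion lines, Benjamini–Hochberg
adjusted across sites. Significant sites (padj < 0.01, log2FC > 1, with a
pseudocount of 10⁻³ on the proportions) must be A→G/T→C changes, show EP
below ~0.9 in both conditions (SNP guard), and carry ≥ 10 fusion reads.

**Motif scanning.** Each motif is a log2-odds PWM against background
letter frequencies (A 0.273, C 0.165, G 0.173, U 0.389):
`PWM[b,j] = log2(p(b,j)/p(b))` with a small pseudo-frequency. Matches are
windows scoring ≥ 4 on either strand — for short motifs essentially exact
matches. Geography statistics use a *matched background*: random sites in
non-target genes reproducing the anchors' gene-body feature and
relative-position histogram (10 bins per feature) exactly.

**Classification.** Counts of each catalogue motif in three
transcript-strand windows around each site ('at' ±10 nt, 'up' and 'down'
50 nt flanks), truncated at 10 and standardized on training rows, feed a
gradient-boosted tree ensemble (learning rate 0.05, depth 6, ≤ 2000 trees,
5-fold CV tree selection, one fifth held out). AUC is the Mann–Whitney
rank statistic.

## Worked example

```python
import tribeclip as tc

config = tc.SimConfig(n_genes=120, seed=7)
bundle, truth = tc.simulate_genome(config)
matrix = tc.simulate_editing_counts(bundle, truth["m6a"], config)

calls = tc.test_differential_editing(matrix, min_support=4, alpha=0.01, lfc_min=1.0)
sites = tc.filter_calls(calls[calls["significant"]])
annotated = tc.annotate_sites(sites, bundle, truth["tpm"])
print(f"{len(sites)} significant edit sites in "
      f"{annotated['gene_id'].nunique()} genes "
      f"(mean editing proportion {sites['ep_fusion'].mean():.3f})")

matches = tc.scan_genome(tc.iupac_pwm("UNUNU"), bundle.seqs, min_score=4)
anchors = tc.annotate_sites(truth["m6a"].drop(columns="gene_id"), bundle, truth["tpm"])
non_targets = sorted(set(bundle.genes["gene_id"]) - set(truth["targets"]))
background = tc.matched_background(anchors, bundle, non_targets, seed=7)
profile = tc.motif_distance_profile(matches, anchors, bundle,
                                    background=background, half_window=50)
peak = profile.loc[profile["per_1000"].idxmax()]
print(f"UNUNU peak: offset {int(peak['offset'])} nt, "
      f"{peak['per_1000']:.0f} motifs per 1000 sites "
      f"(background {peak['background_per_1000']:.0f})")
```

This prints:

```
91 significant edit sites in 30 genes (mean editing proportion 0.241)
UNUNU peak: offset -13 nt, 517 motifs per 1000 sites (background 157)
```

The caller recovers the planted edit sites at low editing proportions; the
UNUNU distance profile peaks inside the U-rich island planted 5' of the
methylation sites (the generator plants the 5-mer starting at −15, so its
occupancy plateau spans offsets −15…−11), while the location-matched
background stays flat.

A thin CLI covers the headline stages:

```sh
tribeclip simulate --outdir sim --seed 1
tribeclip call-editing --counts sim/counts.tsv --samples sim/samples.tsv --out calls.tsv
tribeclip collapse-peaks --bed peaks.bed --out collapsed.bed
tribeclip split-idr --full full.bed --truncated short.bed --outdir idr/
```

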