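"""PWMs, scanning, matched backgrounds, distance profiles, enrichment."""

import numpy as np
import pandas as pd
import pytest

import tribeclip as tc
from tribeclip.genome import bin_of, revcomp
from tribeclip.motifs import (
    DEFAULT_BACKGROUND,
    MOTIF_CATALOGUE,
    build_pwm,
    iupac_pwm,
    scan_genome,
)


class TestPwm:
    def test_all_u_column_entry_closed_form(self):
        pwm = build_pwm(["TTT"] * 10, pseudo=1e-9)
        assert pwm.matrix[0, 3] == pytest.approx(np.log2(1 / 0.389), abs=1e-6)

    def test_column_at_background_frequency_scores_zero(self):
        windows = ["A"] * 273 + ["C"] * 165 + ["G"] * 173 + ["T"] * 389
        pwm = build_pwm(windows, pseudo=1e-4)
        assert np.allclose(pwm.matrix, 0.0, atol=1e-9)

    def test_double_background_frequency_scores_one(self):
        # A at frequency 0.546 vs background 0.273 -> log2(2) = 1
        windows = ["A"] * 546 + ["C"] * 165 + ["G"] * 173 + ["T"] * 116
        pwm = build_pwm(windows, pseudo=1e-9)
        assert pwm.matrix[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["AA", "AAA"])

    def test_entries_finite_after_pseudocount(self):
        for name, pwm in tc.load_catalogue().items():
            assert np.isfinite(pwm.matrix).all()
            assert len(pwm) == len(MOTIF_CATALOGUE[name][0])

    def test_catalogue_has_48_motifs(self):
        assert len(MOTIF_CATALOGUE) == 48

    def test_catalogue_tsv_round_trip(self, tmp_path):
        from tribeclip.motifs import read_catalogue, write_catalogue

        write_catalogue(tmp_path / "cat.tsv")
        assert read_catalogue(tmp_path / "cat.tsv") == MOTIF_CATALOGUE


def brute_force_matches(pwm, seq, min_score):
    """Independent oracle: enumerate every window on both strands."""
    import numpy as np
    from tribeclip.motifs import encode

    length = len(pwm)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        enc = encode(s)
        if enc.size < length:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, length)
        ok = (windows < 4).all(axis=1)
        scores = np.where(
            ok,
            pwm.matrix[np.arange(length)[None, :], np.clip(windows, 0, 3)].sum(
                axis=1
            ),
            -np.inf,
        )
        for i in np.flatnonzero(scores >= min_score):
            start = i if strand == "+" else len(s) - length - i
            out.append((int(start), strand, round(float(scores[i]), 9)))
    return set(out)


class TestScan:
    def test_planted_exact_drach_found(self):
        seq = "C" * 30 + "GGACT" + "C" * 25
        m = scan_genome(iupac_pwm("DRACH"), {"c": seq}, min_score=4)
        plus = m[m["strand"] == "+"]
        assert 30 in plus["start"].tolist()

    def test_matches_equal_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        pwm = iupac_pwm("DRACH")
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 500, p=DEFAULT_BACKGROUND))
            m = scan_genome(pwm, {"c": seq}, min_score=4)
            got = {
                (int(r["start"]), r["strand"], round(float(r["score"]), 9))
                for _, r in m.iterrows()
            }
            assert got == brute_force_matches(pwm, seq, 4)

    def test_no_threshold_counts_all_windows(self):
        seq = "ACGTACGTAC"
        pwm = iupac_pwm("NNN")
        m = scan_genome(pwm, {"c": seq}, min_score=-np.inf)
        assert len(m) == 2 * (len(seq) - 3 + 1)

    def test_empty_sequence_set_gives_empty_table(self):
        assert len(scan_genome(iupac_pwm("DRACH"), {})) == 0

    def test_sequence_shorter_than_motif_skipped(self):
        assert len(scan_genome(iupac_pwm("DRACH"), {"c": "ACG"})) == 0

    def test_reverse_complement_symmetry(self, small_sim):
        """Scanning the reverse-complemented genome with the same PWM gives
        the match set with strands flipped and coordinates mirrored."""
        _, bundle, _ = small_sim
        chrom = "chr1"
        seq = bundle.seqs[chrom][:5000]
        pwm = iupac_pwm("DRACH")
        fwd = scan_genome(pwm, {"c": seq})
        rev = scan_genome(pwm, {"c": revcomp(seq)})
        n = len(seq)
        mirrored = {
            (n - int(r["end"]), {"+": "-", "-": "+"}[r["strand"]],
             round(float(r["score"]), 9))
            for _, r in rev.iterrows()
        }
        got = {
            (int(r["start"]), r["strand"], round(float(r["score"]), 9))
            for _, r in fwd.iterrows()
        }
        assert got == mirrored


@pytest.fixture(scope="module")
def annotated_anchors():
    cfg = tc.SimConfig(n_genes=120, seed=2)
    bundle, truth = tc.simulate_genome(cfg)
    anchors = tc.annotate_sites(
        truth["m6a"].drop(columns="gene_id"), bundle, truth["tpm"]
    )
    non_targets = sorted(set(bundle.genes["gene_id"]) - set(truth["targets"]))
    return bundle, truth, anchors, non_targets


class TestMatchedBackground:
    def test_histogram_preserved_exactly_and_no_target_leak(
        self, annotated_anchors
    ):
        bundle, truth, anchors, non_targets = annotated_anchors
        targets = set(truth["targets"])
        for seed in range(3):
            bg = tc.matched_background(anchors, bundle, non_targets, seed=seed)
            assert len(bg) == len(anchors)
            ah = pd.MultiIndex.from_arrays(
                [anchors["feature"], bin_of(anchors["rel_pos"].to_numpy(), 10)]
            ).value_counts().sort_index()
            bh = pd.MultiIndex.from_arrays(
                [bg["feature"], bin_of(bg["rel_pos"].to_numpy(), 10)]
            ).value_counts().sort_index()
            assert ah.equals(bh)
            assert not bg["gene_id"].isin(targets).any()

    def test_fixed_seed_reproducible(self, annotated_anchors):
        bundle, _, anchors, non_targets = annotated_anchors
        bg1 = tc.matched_background(anchors, bundle, non_targets, seed=7)
        bg2 = tc.matched_background(anchors, bundle, non_targets, seed=7)
        pd.testing.assert_frame_equal(bg1, bg2)

    def test_unfillable_background_raises(self, annotated_anchors):
        bundle, _, anchors, _ = annotated_anchors
        with pytest.raises(ValueError, match="no non-target positions"):
            tc.matched_background(anchors, bundle, [], seed=0)


class TestDistanceProfile:
    def test_planted_flank_peaks_at_declared_offset(self, annotated_anchors):
        bundle, truth, anchors, non_targets = annotated_anchors
        matches = scan_genome(iupac_pwm("UNUNU"), bundle.seqs)
        bg = tc.matched_background(anchors, bundle, non_targets, seed=1)
        prof = tc.motif_distance_profile(
            matches, anchors, bundle, background=bg, half_window=40
        ).set_index("offset")
        # strong enrichment across the planted span relative to background
        # (the default flank model also plants UNUNU-like URUAY at -21, so
        # the global maximum may sit anywhere in the 5' island)
        bg_level = prof["background_per_1000"]
        assert prof.loc[-15, "per_1000"] > bg_level.mean() + 4 * bg_level.std()
        assert prof.loc[-15, "per_1000"] > 2 * bg_level.mean()

    def test_background_profile_statistically_flat(self, annotated_anchors):
        bundle, _, anchors, non_targets = annotated_anchors
        matches = scan_genome(iupac_pwm("UNUNU"), bundle.seqs)
        bg = tc.matched_background(anchors, bundle, non_targets, seed=1)
        prof = tc.motif_distance_profile(
            matches, anchors, bundle, background=bg, half_window=40
        )
        vals = prof["background_per_1000"]
        assert vals.max() <= vals.mean() + 4 * vals.std()

    def test_absent_motif_gives_zero_profile(self, annotated_anchors):
        bundle, _, anchors, _ = annotated_anchors
        empty = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "score", "motif"]
        )
        prof = tc.motif_distance_profile(empty, anchors, bundle, half_window=10)
        assert (prof["per_1000"] == 0).all()

    def test_shifts_beyond_gene_ends_drop_from_denominator(self, toy_bundle):
        from tribeclip.genome import make_site_table

        anchors = make_site_table(["c1"], [30], ["+"], [1], "a")
        anchors = tc.annotate_sites(anchors, toy_bundle)
        empty = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "score", "motif"]
        )
        prof = tc.motif_distance_profile(
            empty, anchors, toy_bundle, half_window=10
        ).set_index("offset")
        assert prof.loc[0, "n_eligible"] == 1
        assert prof.loc[5, "n_eligible"] == 0  # pos 35 is intergenic

    def test_empty_anchor_table_raises(self, annotated_anchors):
        bundle, _, anchors, _ = annotated_anchors
        with pytest.raises(ValueError):
            tc.motif_distance_profile(
                pd.DataFrame(columns=anchors.columns),
                anchors.iloc[0:0],
                bundle,
            )


class TestGenebodyEnrichment:
    def test_uniform_matches_give_flat_bins(self, annotated_anchors):
        bundle, _, _, _ = annotated_anchors
        rng = np.random.default_rng(0)
        bg = bundle.random_transcript_positions(60_000, rng)
        matches = pd.DataFrame(
            {
                "chrom": bg["chrom"], "start": bg["pos0"],
                "end": bg["pos0"] + 1, "strand": bg["strand"],
                "score": 0.0, "motif": "UNIFORM",
            }
        )
        oe = tc.genebody_enrichment(matches, bundle, n_background=300_000, seed=1)
        assert oe["enrichment"].between(0.9, 1.1).all()

    def test_three_utr_planted_motif_enriches_three_utr(self, annotated_anchors):
        bundle, truth, _, _ = annotated_anchors
        m6a = truth["m6a"]
        matches = pd.DataFrame(
            {
                "chrom": m6a["chrom"], "start": m6a["pos0"],
                "end": m6a["pos0"] + 1, "strand": m6a["strand"],
                "score": 0.0, "motif": "PLANTED",
            }
        )
        oe = tc.genebody_enrichment(matches, bundle, n_background=300_000, seed=1)
        assert oe[oe["feature"] == "3UTR"]["enrichment"].mean() > 1.5
        assert (oe[oe["feature"] == "CDS"]["enrichment"].fillna(0) < 1).all()

    def test_background_size_floor_enforced(self, annotated_anchors):
        bundle, truth, _, _ = annotated_anchors
        m6a = truth["m6a"]
        matches = pd.DataFrame(
            {"chrom": m6a["chrom"], "start": m6a["pos0"], "end": m6a["pos0"] + 1,
             "strand": m6a["strand"], "score": 0.0, "motif": "x"}
        )
        with pytest.raises(ValueError):
            tc.genebody_enrichment(matches, bundle, n_background=100)


class TestSplitAnchorProfiles:
    def test_near_far_boundary_at_25nt(self, annotated_anchors):
        bundle, truth, anchors, _ = annotated_anchors
        from tribeclip.genome import make_site_table

        first = anchors.iloc[[0]]
        cl_near = make_site_table(
            first["chrom"], first["pos0"] + 25, first["strand"], [1], "cl"
        )
        cl_far = make_site_table(
            first["chrom"], first["pos0"] + 26, first["strand"], [1], "cl"
        )
        matches = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "score", "motif"]
        )
        near = tc.split_anchor_profiles(
            first, [first["gene_id"].iloc[0]], cl_near, matches, bundle
        )
        far = tc.split_anchor_profiles(
            first, [first["gene_id"].iloc[0]], cl_far, matches, bundle
        )
        assert "target_near" in near and "target_far" not in near
        assert "target_far" in far and "target_near" not in far

    def test_non_target_anchors_emit_only_that_stratum(self, annotated_anchors):
        bundle, truth, anchors, _ = annotated_anchors
        matches = pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "score", "motif"]
        )
        profs = tc.split_anchor_profiles(
            anchors, [], truth["crosslinks"], matches, bundle
        )
        assert set(profs) == {"non_target"}
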