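import numpy as np
import pandas as pd
import pytest

import tribeclip as tc


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded synthetic dataset shared across tests."""
    cfg = tc.SimConfig(n_genes=60, seed=1)
    bundle, truth = tc.simulate_genome(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    cfg, bundle, truth = small_sim
    return tc.simulate_editing_counts(bundle, truth["m6a"], cfg)


@pytest.fixture(scope="session")
def small_calls(small_matrix):
    return tc.test_differential_editing(small_matrix)


@pytest.fixture(scope="session")
def small_sig(small_calls):
    return tc.filter_calls(small_calls[small_calls["significant"]])


@pytest.fixture(scope="session")
def catalogue():
    return tc.load_catalogue()


@pytest.fixture()
def toy_bundle():
    """One plus-strand and one minus-strand gene on a hand-built contig."""
    seq_plus = "ACGTACGTAC" + "ATGGCCAAGTGA" + "TTTATTTTTT"  # 10/12/10
    # minus-strand gene occupying 40..72 of the contig
    genes = pd.DataFrame(
        [
            {
                "gene_id": "GP", "chrom": "c1", "strand": "+",
                "start": 0, "end": 32,
                "5UTR_start": 0, "5UTR_end": 10,
                "CDS_start": 10, "CDS_end": 22,
                "3UTR_start": 22, "3UTR_end": 32,
            },
            {
                "gene_id": "GM", "chrom": "c1", "strand": "-",
                "start": 40, "end": 72,
                "5UTR_start": 62, "5UTR_end": 72,
                "CDS_start": 50, "CDS_end": 62,
                "3UTR_start": 40, "3UTR_end": 50,
            },
        ]
    )
    filler = "GGGGCCCC"
    rest = "TACGTACGTA" * 4
    contig = seq_plus + filler + rest[: 72 - 40] + "AAAA"
    return tc.GenomeBundle(seqs={"c1": contig}, genes=genes)


def site_key(df):
    return set(map(tuple, df[["chrom", "pos0", "strand"]].to_numpy()))
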