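import numpy as np
import pandas as pd
import pytest

from grcscan import simulate


@pytest.fixture(scope="session")
def demo_dataset():
    """Small shared dataset: 150 kb chromosome, 10 genes of 6 kb, two GRC
    genes (c=9 and c=308) at f=0.364, 30x soma depth, no sequencing error."""
    reference, annotation = simulate.simulate_genome(1, 150_000, 10, gc_profile=0.45, seed=11)
    grc = simulate.GrcModel(
        grc_fraction=0.364,
        genes=(
            simulate.GrcGene("gene0003", 9, 0.01),
            simulate.GrcGene("gene0007", 308, 0.01),
        ),
        grc_size_mb=167.3,
    )
    return simulate.simulate_pileups(reference, annotation, grc, depth_soma=30.0, seed=12)


@pytest.fixture(scope="session")
def null_dataset():
    """Same genome, no GRC genes: both tissues differ only by sampling noise."""
    reference, annotation = simulate.simulate_genome(1, 150_000, 10, gc_profile=0.45, seed=11)
    grc = simulate.GrcModel(grc_fraction=0.364, genes=())
    return simulate.simulate_pileups(reference, annotation, grc, depth_soma=30.0, seed=13)


def make_pileup_pair(ref_seq, germ_cols, soma_cols):
    """Build single-chromosome pileups from explicit per-position columns.

    ``germ_cols``/``soma_cols`` map position -> dict(base -> count); all other
    positions get clean reference-only coverage of 30 reads.
    """
    from grcscan.simulate import BASE_INDEX, seq_to_index

    L = len(ref_seq)
    ridx = seq_to_index(ref_seq)
    germ = np.zeros((L, 4), dtype=np.int32)
    soma = np.zeros((L, 4), dtype=np.int32)
    germ[np.arange(L), ridx] = 30
    soma[np.arange(L), ridx] = 30
    for cols, mat in ((germ_cols, germ), (soma_cols, soma)):
        for pos, bases in cols.items():
            mat[pos] = 0
            for base, n in bases.items():
                mat[pos, BASE_INDEX[base]] = n
    return {"chr1": germ}, {"chr1": soma}
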