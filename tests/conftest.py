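import numpy as np
import pytest

from senestack import motifcensus, synthdata


@pytest.fixture(scope="session")
def library_308():
    """The screen's library layout: 70 genes x 4 guides + 28 controls."""
    return synthdata.make_library_manifest(70, 4, 28)


@pytest.fixture(scope="session")
def paused_transcriptome():
    """Three transcripts with a single strong tryptophan pause.

    Tryptophan is excluded from the background codon pool so the pause codon
    is the only W instance, giving the metagene profile a unique anchor.
    """
    return synthdata.make_transcriptome(
        n_transcripts=3,
        n_codons=100,
        pauses=[("tx0000", 20, "W", 50.0)],
        seed=2,
        background_aas="ACDEFGHIKLMNPQRSTVY",
    )


@pytest.fixture(scope="session")
def paused_rpf(paused_transcriptome):
    return synthdata.simulate_rpf(paused_transcriptome, depth=100_000, seed=3)


@pytest.fixture(scope="session")
def null_motif_pvalues():
    """Chi-square p-values from 500 equal-rate protein-set replicates."""
    rule = motifcensus.MotifSet.rule()
    pvals = []
    for rep in range(500):
        set_a, set_b = synthdata.simulate_protein_sets(
            50, 50, length=300, motif_rate_a=0.02, motif_rate_b=0.02, seed=20_000 + rep
        )
        cen = motifcensus.census(set_a, set_b, rule)
        pvals.append(motifcensus.compare_sets(cen).pvalue)
    return np.asarray(pvals)
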