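import numpy as np
import pytest

from seqshave import Alignment, generate_fixture_msa, translate_alignment


@pytest.fixture
def identical_aa_msa():
    """Ten identical gapless protein sequences."""
    seq = "MKVLITGAGSGIGLEAARQAVAEGARVVLADI"
    return Alignment(tuple((f"s{i}", seq) for i in range(10)), "aa")


@pytest.fixture
def conserved_fixture_aa():
    """A 25-sequence, moderately conserved synthetic protein alignment."""
    nt = generate_fixture_msa(
        n_seqs=25, n_codons=150, divergence=0.03, indel_rate=0.0, rng_seed=7
    )
    return translate_alignment(nt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
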