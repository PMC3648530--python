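import numpy as np
import pytest

from divergescan.synthetic_data import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small-but-complete simulation parameters for fast tests."""
    return SimParams(
        seed=42,
        n_contigs=300,
        contig_length_range=(500, 3000),
        n_planted_conserved=2,
        n_planted_diverged=2,
        read_count=200,
        pileup_n_contigs=2,
        pileup_span=400,
    )


@pytest.fixture
def default_params():
    return SimParams(seed=7)
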