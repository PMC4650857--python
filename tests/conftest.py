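import numpy as np
import pytest
from hypothesis import settings

from motifdiff.model import DNA, PROTEIN, random_motif

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def dna():
    return DNA


@pytest.fixture
def protein():
    return PROTEIN


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_distribution(rng, size=4, concentration=1.0):
    return rng.dirichlet([concentration] * size)


@pytest.fixture
def dna_motifs():
    """Five reproducible random DNA motifs of length 6."""
    return [random_motif(DNA, 6, 1.0, seed=s, label=f"m{s}") for s in range(5)]
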