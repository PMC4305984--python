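import random

import numpy as np
import pytest

from wdsvr.seqdata import AffinityDataset


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def random_pairs(rng):
    """30 random length-12 sequence pairs for kernel oracle checks."""
    return [(random_dna(rng, 12), random_dna(rng, 12)) for _ in range(30)]


@pytest.fixture
def small_dataset(rng):
    """40 random 10-mers with lognormal affinities."""
    nprng = np.random.default_rng(99)
    seqs = [random_dna(rng, 10) for _ in range(40)]
    affs = np.exp(nprng.normal(3.0, 0.5, size=40))
    return AffinityDataset.from_arrays(seqs, affs)
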