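import numpy as np
import pytest

from hicdelta.genome import BinTable, GenomeSpec
from hicdelta.matrix import ContactMap


@pytest.fixture
def two_chrom_genome():
    return GenomeSpec(["c1", "c2"], [25_000_000, 25_000_000])


@pytest.fixture
def small_bins():
    return BinTable(GenomeSpec(["c1"], [2_000_000]), 100_000)


def random_symmetric_counts(n, rng, scale=50.0):
    """Dense positive symmetric count-like matrix."""
    A = rng.gamma(2.0, scale, size=(n, n))
    return np.triu(A) + np.triu(A, 1).T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def balanced_map_from(bins, counts):
    """Wrap a matrix as an already-balanced ContactMap (unit biases)."""
    return ContactMap(bins, counts, balanced=True, bias=np.ones(len(bins)))
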