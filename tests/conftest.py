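import numpy as np
import pytest

from landgen.genotypes import GenotypeTable
from landgen.raster import Raster


@pytest.fixture
def toy_table():
    """Five samples, three loci; includes missing calls and a duplicate
    genotype pair (s0/s1 identical, s2 differs from s0 at one locus)."""
    calls = np.array(
        [
            [[100, 102], [200, 200], [300, 302]],  # s0
            [[100, 102], [200, 200], [300, 302]],  # s1 == s0
            [[100, 102], [200, 202], [300, 302]],  # s2: 1 mismatch vs s0
            [[104, 104], [204, 204], [0, 0]],      # s3: distinct, 1 missing locus
            [[100, 104], [200, 204], [302, 304]],  # s4
        ]
    )
    xy = np.array([[0, 0], [1000, 0], [0, 1000], [5000, 5000], [2000, 2000]], float)
    return GenotypeTable(
        ["s0", "s1", "s2", "s3", "s4"],
        ["F", "F", "M", "M", "unknown"],
        xy,
        calls,
        ["locA", "locB", "locC"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_table(rng, n=12, n_loci=5, n_alleles=4, missing_rate=0.1):
    sizes = 100 + 2 * np.arange(n_alleles)
    calls = rng.choice(sizes, size=(n, n_loci, 2))
    miss = rng.uniform(size=(n, n_loci)) < missing_rate
    calls[miss] = 0
    # ensure every sample typed somewhere and co-typing guaranteed at locus 0
    calls[:, 0, :] = rng.choice(sizes, size=(n, 2))
    xy = rng.uniform(0, 10000, size=(n, 2))
    return GenotypeTable(
        [f"i{k}" for k in range(n)],
        list(rng.choice(["F", "M"], size=n)),
        xy,
        calls,
        [f"L{j}" for j in range(n_loci)],
    )


@pytest.fixture
def uniform_surface():
    return Raster(np.ones((8, 10)), 0.0, 0.0, 100.0, -9999.0)
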