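import numpy as np
import pytest

from fuzzgga import Dataset, FuzzyChromosome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def four_corners():
    """Four points in a unit diamond around (1, 0) — zero-mean scatter 0.5 I."""
    return Dataset(points=np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0], [1.0, -1.0]]))


@pytest.fixture
def line_1d():
    """The 1-D quartet {0, 1, 9, 10}: two tight pairs far apart."""
    return Dataset(points=np.array([[0.0], [1.0], [9.0], [10.0]]))


@pytest.fixture
def crisp_pairs():
    """Crisp 2-partition {0,1 | 9,10} of the 1-D quartet."""
    return FuzzyChromosome(
        np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
    )


def random_valid_chromosome(rng, k, n):
    """Random fuzzy partition with simplex columns (valid for tests)."""
    U = rng.dirichlet(np.ones(k), size=n).T
    return FuzzyChromosome(U)
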