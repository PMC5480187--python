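import numpy as np
import pytest

from pathdist.evaluate import Partition
from pathdist.io import DistanceMatrix, ExpressionMatrix, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def sample_ids(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def random_distance(rng, n: int) -> DistanceMatrix:
    """A random symmetric nonnegative matrix with zero diagonal."""
    a = rng.uniform(0.1, 5.0, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(sample_ids(n), a)


def random_partition(rng, n: int, k: int) -> Partition:
    """A random partition of n samples into exactly k nonempty clusters."""
    while True:
        labels = rng.integers(1, k + 1, size=n)
        if len(np.unique(labels)) == k:
            from pathdist.evaluate import relabel_first_appearance

            return Partition(sample_ids(n), relabel_first_appearance(labels))


@pytest.fixture
def small_expr(rng):
    values = rng.normal(size=(10, 6))
    return ExpressionMatrix(
        [f"G{i}" for i in range(10)], sample_ids(6), values
    )


@pytest.fixture
def three_sets():
    return GeneSetCollection(
        {"P1": ["G0", "G1", "G2"], "P2": ["G3", "G4"], "P3": ["G8", "G9", "GX"]}
    )
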