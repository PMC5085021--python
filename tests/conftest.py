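import numpy as np
import pytest

from ecgc import TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 40 x 3 matrix of independent Gaussian noise."""
    return TimeSeriesMatrix(
        values=rng.standard_normal((40, 3)), names=("a", "b", "c")
    )


def standardized_design(rng, n, m):
    """Random design with columns standardized to mean 0 / variance 1."""
    X = rng.standard_normal((n, m))
    return (X - X.mean(axis=0)) / X.std(axis=0)
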