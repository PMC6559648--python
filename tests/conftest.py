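import logging

import numpy as np
import pytest

from trifactor import DataMatrix, FactorTriple

# pinv-fallback warnings from ALS on degenerate random instances are expected
logging.getLogger("trifactor.optimizers").setLevel(logging.ERROR)


def random_instance(rng, n, m, k1, k2, positive=True):
    """A random data matrix and conforming random factors."""
    X = DataMatrix(rng.random((n, m)) + (0.1 if positive else 0.0))
    F = FactorTriple(
        rng.random((n, k1)) + 0.1,
        rng.random((k1, k2)) + 0.1,
        rng.random((m, k2)) + 0.1,
    )
    return X, F


def random_instances(seed=0, count=20, n=12, m=9, k1=3, k2=4):
    rng = np.random.default_rng(seed)
    return [random_instance(rng, n, m, k1, k2) for _ in range(count)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def exact_instance(rng):
    """X built exactly as U S V^T, so every solver is at a fixed point.

    Ranks are equal and S is full-rank: the ALS normal matrices are then
    invertible, which the ALS fixed-point property requires (with k1 != k2
    the S-side solve is underdetermined and the pseudo-inverse picks the
    minimum-norm solution rather than the incumbent factor).
    """
    U = rng.random((10, 3)) + 0.1
    S = rng.random((3, 3)) + 0.1 + np.eye(3)
    V = rng.random((8, 3)) + 0.1
    F = FactorTriple(U, S, V)
    return DataMatrix(F.reconstruct()), F
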