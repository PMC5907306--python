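import numpy as np
import pytest

from ddinmf import SignedAdjacency, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_signed_adjacency(m: int, rng, density: float = 0.3) -> SignedAdjacency:
    """Random symmetric signed adjacency, used across test modules."""
    upper = np.triu(rng.random((m, m)) < density, k=1)
    signs = np.where(rng.random((m, m)) < 0.5, 1, -1)
    mat = np.where(upper, signs, 0)
    mat = mat + mat.T
    return SignedAdjacency(mat, [f"d{i:03d}" for i in range(m)])


@pytest.fixture
def small_benchmark():
    return generate_benchmark("small", seed=7)
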