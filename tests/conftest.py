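import numpy as np
import pytest

from nmfpost import ExpressionMatrix, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng) -> ExpressionMatrix:
    """20 genes x 10 samples of positive noise, no structure."""
    values = rng.uniform(0.5, 5.0, size=(20, 10))
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(20)], [f"s{j}" for j in range(10)]
    )


@pytest.fixture(scope="session")
def easy_dataset():
    """Small, clearly separable 3-cluster Poisson dataset (fast to fit)."""
    return generate(
        n_signal=60, n_irrelevant=20, m=18, k=3,
        expression_scale=50.0, dominance=5.0, seed=7,
    )


@pytest.fixture
def random_factors(rng):
    """A batch of random positive (W, H) pairs of varied shapes."""
    pairs = []
    for _ in range(20):
        n = int(rng.integers(4, 15))
        m = int(rng.integers(3, 12))
        k = int(rng.integers(1, min(n, m)))
        pairs.append(
            (rng.uniform(0.05, 3.0, size=(n, k)), rng.uniform(0.05, 3.0, size=(k, m)))
        )
    return pairs
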