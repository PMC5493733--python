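import numpy as np
import pytest

from agbridge.design import make_design


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


def random_design(rng, n=40, group_sizes=(2, 2, 2), noise=0.5, sparse=True):
    """Small partially linear dataset with known grouped truth."""
    group_sizes = np.asarray(group_sizes, dtype=int)
    P = int(group_sizes.sum())
    X = rng.standard_normal((n, P))
    u = rng.uniform(0.0, 1.0, n)
    beta = rng.standard_normal(P)
    if sparse:
        mask = rng.integers(0, 2, len(group_sizes))
        if mask.sum() == 0:
            mask[0] = 1
        beta = beta * np.repeat(mask, group_sizes)
    y = X @ beta + np.cos(2 * np.pi * u) + noise * rng.standard_normal(n)
    return make_design(y, X, u, group_sizes), beta


@pytest.fixture
def small_design(rng):
    design, beta = random_design(rng)
    return design
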