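import numpy as np
import pytest

from proteograph import SimulationConfig, generate_dataset


def random_psd_instance(rng, p=None, n=None, m=None):
    """A small random model instance: network, expression, clusters, labels."""
    p = p or int(rng.integers(4, 11))
    n = n or int(rng.integers(5, 13))
    m = m or int(rng.integers(2, min(5, p // 2 + 1)))
    W = rng.random((p, p)) * (rng.random((p, p)) < 0.5)
    W = np.triu(W, 1)
    W = W + W.T
    X = rng.random((p, n))
    perm = rng.permutation(p)
    bounds = sorted(rng.choice(np.arange(1, p), size=m - 1, replace=False)) if m > 1 else []
    clusters = [sorted(perm[a:b].tolist()) for a, b in zip([0] + list(bounds), list(bounds) + [p])]
    Y = rng.integers(0, 2, size=(3, n))
    # ensure both classes per subtype
    for s in range(3):
        if Y[s].sum() == 0:
            Y[s, 0] = 1
        if Y[s].sum() == n:
            Y[s, 0] = 0
    return W, X, clusters, Y


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic cohort reused by estimator-level tests."""
    return generate_dataset(SimulationConfig(p=20, m=4, n=240, seed=5, noise_sd=0.0))
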