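import numpy as np
import pytest

from gomclust import CountMatrix, SimulationConfig, simulate_gom_counts


def random_count_matrix(
    rng: np.random.Generator, n: int = 10, g: int = 20, lam: float = 5.0
) -> CountMatrix:
    """Poisson counts with every sample guaranteed at least one read."""
    counts = rng.poisson(lam, size=(n, g))
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] = 1
    return CountMatrix(
        counts,
        [f"s{i}" for i in range(n)],
        [f"g{j}" for j in range(g)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_counts(rng):
    return random_count_matrix(rng)


@pytest.fixture(scope="session")
def simulated_k3():
    """A moderately separated K=3 dataset with ground truth, shared across tests."""
    cfg = SimulationConfig(
        N=60, G=120, K=3, library_size=2000, membership_regime="mixed",
        profile_separation=1.5, seed=101,
    )
    m, q, theta = simulate_gom_counts(cfg)
    return cfg, m, q, theta
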