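import numpy as np
import pandas as pd
import pytest

from coexnet import SimConfig, build_network, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact two-species study with clear planted structure."""
    cfg = SimConfig(
        seed=7,
        n_genes_per_species=400,
        module_sizes=(30, 40, 50),
        shared_module_flags=(True, True, False),
        trait_loading=(0.8, 0.0, 0.0),
        de_effect=(0.0, 2.0, 0.0),
        within_module_loading_range=(0.8, 1.0),
        noise_sd=0.6,
    )
    return cfg, generate_study(cfg)


@pytest.fixture(scope="session")
def small_network(small_study):
    _, (expr_a, _, _, _, _) = small_study
    return build_network(expr_a, power=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_symmetric_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """A valid unsigned adjacency: symmetric, in [0, 1], unit diagonal."""
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def block_expression(
    rng: np.random.Generator,
    block_sizes,
    n_samples: int = 60,
    loading: float = 3.0,
    noise_sd: float = 1.0,
    n_background: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression with independent-factor blocks plus background noise rows."""
    rows, labels = [], []
    for b, size in enumerate(block_sizes, start=1):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(loading * f + rng.normal(scale=noise_sd, size=n_samples))
            labels.append(b)
    for _ in range(n_background):
        rows.append(rng.normal(size=n_samples))
        labels.append(0)
    expr = pd.DataFrame(rows, index=[f"g{i:04d}" for i in range(len(rows))])
    return expr, np.array(labels)
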