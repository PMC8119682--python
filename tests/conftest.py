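import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Three planted modules, 100 samples: fast shared recovery fixture."""
    from coexnet import synth

    cfg = synth.SyntheticConfig(
        n_genes=500, n_samples=100, module_sizes=(120, 90, 60),
        loading_range=(0.7, 0.95),
        trait_specs=(synth.TraitSpec("trait_m1", 1, 0.8),),
        seed=7,
    )
    values, truth = synth.simulate_expression(cfg)
    traits = synth.simulate_traits(truth, cfg)
    return cfg, values, truth, traits


@pytest.fixture(scope="session")
def small_network(small_dataset):
    from coexnet import network

    _, values, _, _ = small_dataset
    return network.build_network(values)


def random_symmetric_adjacency(n: int, rng) -> np.ndarray:
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a
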