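import numpy as np
import pytest

from circaphase.simdata import NetSimConfig, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic simulated study: 800 genes, 10% cyclers."""
    cfg = SimConfig(
        n_genes=800,
        frac_cycling_18=0.1,
        frac_cycling_25=0.1,
        frac_shared=0.5,
        seed=42,
    )
    mats, truth = simulate_study(cfg)
    return cfg, mats, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def ws_config():
    return NetSimConfig(n_nodes=200, graph_model="watts-strogatz", seed=7)
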