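import numpy as np
import pytest

from beliefspot import SimulationConfig, simulate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_field():
    """Small clean field: 8 bright + 8 dim well-separated sources."""
    cfg = SimulationConfig(
        height=256,
        width=256,
        n_bright=8,
        n_dim=8,
        gauss_sigma_frac=0.0,
        poisson_lambda_frac=0.0,
        min_separation=40,
        seed=7,
    )
    return simulate_image(cfg)


@pytest.fixture(scope="session")
def noisy_field():
    """Baseline-noise field at the standard condition."""
    cfg = SimulationConfig(
        height=256, width=256, n_bright=8, n_dim=8, min_separation=30, seed=11
    )
    return simulate_image(cfg)
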