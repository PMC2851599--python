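import numpy as np
import pytest

from estmine import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free synthetic data set: exact marker recovery is expected."""
    cfg = synth.SimulationConfig(
        n_genes=40,
        n_reads=6000,
        base_error_rate=0.0,
        retro_divergence=0.0,
        retro_fraction=0.05,
        contaminant_fraction=0.10,
        seed=42,
    )
    return synth.simulate(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Synthetic data set at the default error/quality settings."""
    cfg = synth.SimulationConfig(n_genes=30, n_reads=3000, seed=7)
    return synth.simulate(cfg)
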