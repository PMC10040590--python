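import numpy as np
import pytest

from gspred import SimulationConfig, simulate_dataset, MCMCSettings


@pytest.fixture(scope="session")
def small_panel():
    """120 lines x 300 markers, two environments, h2=0.5, r_g=0.8."""
    cfg = SimulationConfig(n_lines=120, m_markers=300, h2=0.5, r_g=0.8, seed=42)
    geno, means, truth = simulate_dataset(cfg)
    return cfg, geno, means, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_chain():
    return MCMCSettings(n_iter=1200, burn_in=400, thin=2, seed=7)
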