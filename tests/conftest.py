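import numpy as np
import pytest

from triomed.simulate import SimulationConfig, simulate_trio_data

SEED = 20240917


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_study():
    """A 120-sample, 30-trio study with half the trios null."""
    cfg = SimulationConfig(n_samples=120, n_trios=30, fraction_null=0.5,
                           beta3=0.6, seed=SEED)
    return simulate_trio_data(cfg)


@pytest.fixture(scope="session")
def confounded_study():
    """A study with one strong hidden factor loading on both transcripts."""
    cfg = SimulationConfig(n_samples=200, n_trios=40, fraction_null=1.0,
                           n_hidden=1, confounder_scale=0.9, seed=SEED + 1)
    return simulate_trio_data(cfg)
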