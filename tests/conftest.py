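import numpy as np
import pytest

from lucsim.calibration import MCMCConfig
from lucsim.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """64 x 64 landscape, two calibration periods: fast shared fixture."""
    return SyntheticConfig(grid_rows=64, grid_cols=64, n_periods=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def medium_dataset():
    """120 x 120 landscape with the default four periods."""
    return generate_dataset(SyntheticConfig(grid_rows=120, grid_cols=120, seed=7))


@pytest.fixture()
def fast_mcmc():
    return MCMCConfig(n_iter=1500, burn_in=500, thin=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
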