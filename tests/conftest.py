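import numpy as np
import pytest

from smcfusion import synthetic


@pytest.fixture(scope="session")
def small_config():
    """A fast experiment: 24 plots, 24-px rasters, default couplings."""
    return synthetic.SceneConfig(n_plots=24, raster_size=24, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return synthetic.generate_experiment(small_config)


@pytest.fixture(scope="session")
def default_experiment():
    """The full stated world: 96 plots at default couplings and noise."""
    return synthetic.generate_experiment(synthetic.SceneConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
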