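import numpy as np
import pytest

from sarbiomass.datasets import load_corn_observations
from sarbiomass.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def corn_table():
    return load_corn_observations()


@pytest.fixture(scope="session")
def calibration_records(corn_table):
    return corn_table.calibration


@pytest.fixture(scope="session")
def validation_records(corn_table):
    return corn_table.validation


@pytest.fixture(scope="session")
def noise_free():
    """Noise-free synthetic table over the field-data ranges, with truth."""
    config = SyntheticConfig(noise_cv=0.0, ndvi_noise_sd=0.0, seed=7)
    table, truth = generate(config)
    return config, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
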