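import numpy as np
import pytest

from standcarbon.allometry import fit_allometric_models
from standcarbon.als import fit_area_models
from standcarbon.soil import ClimateYear, DEFAULT_SOIL_PARAMS
from standcarbon.synthetic import SyntheticConfig, gen_landscape, gen_tree_dataset


@pytest.fixture(scope="session")
def zero_config():
    return SyntheticConfig(seed=11, n_stands=40, cells_per_stand=(3, 8)).zero_noise()


@pytest.fixture(scope="session")
def zero_bundle(zero_config):
    return gen_landscape(zero_config)


@pytest.fixture(scope="session")
def zero_trees(zero_config):
    return gen_tree_dataset(zero_config)


@pytest.fixture(scope="session")
def zero_models(zero_bundle, zero_trees):
    return fit_area_models(zero_bundle.plots), fit_allometric_models(zero_trees)


@pytest.fixture(scope="session")
def noisy_bundle():
    return gen_landscape(SyntheticConfig(seed=5, n_stands=40, cells_per_stand=(3, 8)))


@pytest.fixture(scope="session")
def boreal_climate():
    return ClimateYear(precipitation=700.0, temperature=4.0, amplitude=20.0)


@pytest.fixture(scope="session")
def soil_params():
    return DEFAULT_SOIL_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(42)
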