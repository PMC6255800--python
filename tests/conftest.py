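import logging

import numpy as np
import pytest

from odortransfer import ElasticNetConfig
from odortransfer.synthetic import ScenarioConfig, make_scenario

# the permutation/calibration machinery logs per-molecule warnings heavily
logging.getLogger("odortransfer").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast, fully coupled scenario used across test modules."""
    return make_scenario(
        ScenarioConfig(
            n_source_desc=10,
            n_target_desc=40,
            dim=80,
            n_shared_mol=30,
            n_extra_mol=20,
            n_features=120,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Zero-noise variant: every map is exactly identifiable."""
    return make_scenario(
        ScenarioConfig(
            n_source_desc=10,
            n_target_desc=40,
            dim=80,
            n_shared_mol=30,
            n_extra_mol=20,
            n_features=120,
            noise_semantic=0.0,
            noise_ratings=0.0,
            noise_chem=0.0,
            seed=42,
        )
    )


@pytest.fixture()
def unpenalized_config():
    return ElasticNetConfig(lambda1_grid=(0.0,), lambda2_grid=(0.0,))


@pytest.fixture()
def quick_config():
    return ElasticNetConfig(
        lambda1_grid=(0.0, 0.1, 1.0),
        lambda2_grid=(0.0, 1.0),
        inner_folds=3,
        seed=0,
        standardize=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
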