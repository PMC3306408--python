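import numpy as np
import pytest

from hormfit import (
    NaturalParams,
    SimulationConfig,
    fit_model,
    generate_dataset,
)

CRS_TRUTH = NaturalParams(c=0.0, d=100.0, b=2.0, e=10.0, f=50.0, a=1.0)
BC_TRUTH = NaturalParams(c=0.0, d=100.0, b=2.0, e=10.0, f=5.0)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_data(default_config):
    """One replicated dataset from the default Cedergreen scenario,
    inverse-SD weighted."""
    return generate_dataset(default_config).with_weights("inverse_sd")


@pytest.fixture(scope="session")
def crs_fit(default_data):
    """Natural Cedergreen fit of the default dataset (free a)."""
    return fit_model(default_data, "cedergreen")


@pytest.fixture(scope="session")
def bc_data():
    cfg = SimulationConfig(truth_family="brain_cousens",
                           truth_params=BC_TRUTH, seed=11)
    return generate_dataset(cfg).with_weights("inverse_sd")


@pytest.fixture(scope="session")
def bc_fit(bc_data):
    return fit_model(bc_data, "brain_cousens")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
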