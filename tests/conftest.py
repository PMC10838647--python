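import numpy as np
import pytest

from hpaxis import (
    HPAModel,
    default_events,
    default_params,
    default_scheme,
    load_fixture_profiles,
)


@pytest.fixture(scope="session")
def base_params():
    return default_params()


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def events():
    return default_events()


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture_profiles()


@pytest.fixture(scope="session")
def fixture_fit(fixture_data):
    """One fit of the packaged example dataset, shared across tests."""
    model = HPAModel(fixture_data)
    return model.fit(mask=model.default_mask(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
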