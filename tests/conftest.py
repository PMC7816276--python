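import numpy as np
import pytest

from fecolim import IntegrationSettings, ModelParameters, ModelState


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def fast_settings() -> IntegrationSettings:
    """Coarser step for unit tests; accuracy-sensitive tests set their own."""
    return IntegrationSettings(dt=0.05)


@pytest.fixture()
def state(params) -> ModelState:
    return ModelState.initial(dFe=0.5, LDOC=5.0, params=params)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
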