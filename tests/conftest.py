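import numpy as np
import pytest

from catchroll import Environment, ParticleGeometry, preset


@pytest.fixture(scope="session")
def env() -> Environment:
    return Environment()


@pytest.fixture(scope="session")
def geom() -> ParticleGeometry:
    return ParticleGeometry()


@pytest.fixture(scope="session")
def slip_params():
    return preset("slip")


@pytest.fixture(scope="session")
def catch_params():
    return preset("catch")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
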