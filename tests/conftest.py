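import numpy as np
import pytest
from hypothesis import settings

from hoverfall.model import ControllerGains, IMPROVED_GAINS, SimConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

TS = 1.0 / 1600.0


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def basic_gains() -> ControllerGains:
    return ControllerGains()


@pytest.fixture(scope="session")
def improved_gains() -> ControllerGains:
    return IMPROVED_GAINS


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
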