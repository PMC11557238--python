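import numpy as np
import pytest

from pulsechem import Phantom, TrackParams, default_registry
from pulsechem.tracks import StoppingPower


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def stopping():
    return StoppingPower.bundled()


@pytest.fixture(scope="session")
def phantom():
    return Phantom()


@pytest.fixture
def params_10kev():
    return TrackParams(kinetic_energy=1e4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240898)
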