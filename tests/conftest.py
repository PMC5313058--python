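import numpy as np
import pytest

from ranvier.geometry import load_preset, build_axon
from ranvier.cable_model import ChannelKinetics


@pytest.fixture(scope="session")
def optic():
    return load_preset("optic_nerve")


@pytest.fixture(scope="session")
def cortex():
    return load_preset("cortex")


@pytest.fixture(scope="session")
def kinetics():
    return ChannelKinetics()


@pytest.fixture(scope="session")
def optic_chain(optic):
    return build_axon(optic)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170128)
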