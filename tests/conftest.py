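import numpy as np
import pytest

from stdpforage import NetworkConfig, NeuronParams, StdpParams, SynapseParams


@pytest.fixture(scope="session")
def neuron_params():
    return NeuronParams()

@pytest.fixture(scope="session")
def synapse_params():
    return SynapseParams()


@pytest.fixture(scope="session")
def stdp_params():
    return StdpParams()


@pytest.fixture(scope="session")
def small_config():
    """A reduced network (4x4 hidden) for fast structural tests."""
    return NetworkConfig(hidden_side=4, fan_in=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
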