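import numpy as np
import pytest

from motifnet import NeuronParams, SynapseParams
from motifnet.dynamics import init_state


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def syn():
    return SynapseParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def single_neuron_state(neuron, exc=True, V=None):
    """A one-neuron state at a controlled initial condition."""
    state = init_state(np.array([exc]), neuron, rng=None)
    state.V[:] = neuron.E_L_E if V is None else V
    return state
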