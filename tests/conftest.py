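import numpy as np
import pytest

from ffgain import FeedforwardParams, NeuronParams, SimConfig


@pytest.fixture
def noisefree():
    return NeuronParams(sigma=0.0)


@pytest.fixture
def noisy():
    return NeuronParams(sigma=1.0)


@pytest.fixture
def ff_inhibitory():
    return FeedforwardParams(g=-0.6, n=500)


@pytest.fixture
def short_sim():
    """Small, fast simulation window for unit tests."""
    return SimConfig(t_total=2000.0, t_transient=200.0, dt=0.05, seed=1234)
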