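import numpy as np
import pytest

from stipnet import KernelSpec, SpikeTrain, SpikeTrainSet
from stipnet.synthetic import worked_example_fixture

from oracles import random_times

T = 10.0  # simulation interval used throughout the suite (ms)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture
def gaussian40():
    return KernelSpec("gaussian", 40.0)


def make_train(times, interval_end=T):
    return SpikeTrain(times, interval_end)


def make_set(list_of_times, interval_end=T):
    return SpikeTrainSet([SpikeTrain(t, interval_end) for t in list_of_times])


def random_set(rng, n_neurons, max_spikes=6, interval_end=T):
    return make_set([random_times(rng, max_spikes, interval_end)
                     for _ in range(n_neurons)], interval_end)
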