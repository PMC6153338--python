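import dataclasses

import numpy as np
import pytest

from gnburst.core import SpikeTrain
from gnburst.pattern_classifier import Pattern
from gnburst.synthetic_data import STANDARD_PRESETS, CellParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def bursting_preset():
    return STANDARD_PRESETS[Pattern.BURSTING]


@pytest.fixture
def tonic_preset():
    return STANDARD_PRESETS[Pattern.TONIC]


@pytest.fixture
def default_cell():
    return CellParams()


def random_train(rng, n_spikes=None, duration=100.0, neuron_id="rnd"):
    """Poisson-ish random train helper shared across oracle tests."""
    if n_spikes is None:
        n_spikes = int(rng.integers(3, 60))
    times = np.sort(rng.uniform(0.0, duration, size=n_spikes))
    times = times[np.concatenate([[True], np.diff(times) > 0])]
    return SpikeTrain(neuron_id, times, duration)


@pytest.fixture
def make_random_train(rng):
    return lambda **kw: random_train(rng, **kw)
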