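import numpy as np
import pytest
from hypothesis import settings

from periseq import calcium, synth

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return synth.GeneratorConfig()


@pytest.fixture(scope="session")
def session(config):
    """One synthetic session: timeline, planted events, epoch mask, gamma."""
    timeline, truth = synth.gen_timeline(config, seed=5)
    truth = synth.gen_neuron_events(truth, config, seed=5)
    times = np.arange(0, timeline.trial_end, 1 / config.fps)
    mask = timeline.epoch_mask(times)
    return timeline, truth, mask


@pytest.fixture(scope="session")
def gamma():
    return calcium.gamma_from_tau()
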