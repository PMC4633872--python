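import numpy as np
import pytest

from fixsig import SimulationConfig
from fixsig.signature import EpochedEvents
from fixsig.simulate import sample_epoched_trials, synthesize_recording


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_session():
    """A modest synthetic session (blank + high contrast) with ground truth."""
    cfg = SimulationConfig(contrasts=[0.0, 4.0], n_passive=50, n_response=0)
    rec, trials, truth = synthesize_recording(cfg, seed=11)
    return cfg, rec, trials, truth


def epoch_from_generator(config, contrast, n_trials, rng) -> EpochedEvents:
    """Event-level epochs straight from the generator (lossless detection)."""
    times, amps = sample_epoched_trials(config, contrast, n_trials, rng=rng)
    return EpochedEvents(times=times, amps=amps, trial_ids=np.arange(n_trials))
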