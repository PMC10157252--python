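import numpy as np
import pytest

from tuspac import StimulusProtocol, generate_session, state_profile


@pytest.fixture(scope="session")
def short_protocol():
    """A 4-trial protocol at the minimum inter-trial interval (fast tests)."""
    return StimulusProtocol(n_trials=4, inter_trial_interval=10.0)


@pytest.fixture(scope="session")
def anesthesia_session(short_protocol):
    """One short synthetic anesthesia session shared across tests."""
    return generate_session(state_profile("anesthesia"), short_protocol, seed=7)


@pytest.fixture
def tone():
    """1-s unit-amplitude 8 Hz cosine at 1 kHz."""
    t = np.arange(1000) / 1000.0
    return np.cos(2 * np.pi * 8.0 * t)
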