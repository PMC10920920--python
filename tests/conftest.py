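import numpy as np
import pytest

from stridecycle.synth import ParticipantSpec, SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def session_config():
    return SessionConfig()


def deterministic_spec(**kw) -> ParticipantSpec:
    """Participant with all gait randomness switched off."""
    defaults = dict(stride_duration_sd=0.0, head_noise_sd=0.0,
                    tempo_trial_sd=0.0)
    defaults.update(kw)
    return ParticipantSpec("P00", **defaults)


@pytest.fixture
def det_spec():
    return deterministic_spec()
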