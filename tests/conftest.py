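import numpy as np
import pytest
from hypothesis import settings

import emgeca as eg

settings.register_profile("repo", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("repo")


@pytest.fixture(scope="session")
def tiny_protocol():
    """Two gestures, six seconds: the smallest session that still splits."""
    return eg.desk_protocol(duration_s=6.0, reps_range=(2, 3), n_gestures=2,
                            subject_seed=11)


@pytest.fixture(scope="session")
def tiny_session(tiny_protocol):
    return eg.synth_session(tiny_protocol)


@pytest.fixture(scope="session")
def tiny_envelopes(tiny_session):
    return [eg.extract_envelope(r) for r in tiny_session]


@pytest.fixture(scope="session")
def tiny_ws(tiny_envelopes):
    return eg.split_windows(eg.segment_session(tiny_envelopes))


@pytest.fixture(scope="session")
def tiny_trained(tiny_ws):
    spec = eg.compact_spec(tiny_ws.window_len, tiny_ws.n_channels, 2)
    return eg.train_model(spec, tiny_ws, eg.desk_train_config(seed=0, epochs=5))
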