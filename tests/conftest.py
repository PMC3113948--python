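import numpy as np
import pytest

from emgdyn import ProtocolSpec, WindowSpec, generate_session, make_subject, segment


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def small_protocol():
    """A miniature protocol (5 classes, 3 channels, short phases) for
    fast end-to-end tests; same structure as the full default."""
    return ProtocolSpec(
        n_classes=5,
        n_channels=3,
        fs=512,
        reps_per_session=1,
        n_sessions=3,
        ramp_s=1.0,
        hold_s=1.5,
        inter_contraction_rest_s=1.0,
    )


@pytest.fixture(scope="session")
def subject(protocol):
    return make_subject(protocol, seed=7)


@pytest.fixture(scope="session")
def session(subject, protocol):
    return generate_session(subject, protocol, session_index=1)


@pytest.fixture(scope="session")
def series(session):
    return segment(session, WindowSpec())


@pytest.fixture(scope="session")
def small_sessions(small_protocol):
    subject = make_subject(small_protocol, seed=3)
    return subject, [
        generate_session(subject, small_protocol, k)
        for k in range(1, small_protocol.n_sessions + 1)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
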