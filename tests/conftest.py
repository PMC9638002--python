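import numpy as np
import pytest

from ethospike.scoring import score_session
from ethospike.synthetic import SimConfig, simulate_session, simulate_tracking


@pytest.fixture(scope="session")
def small_session():
    """20 units, 2 presentations/class, default gains: the cheap workhorse."""
    cfg = SimConfig(n_units=20, events_per_class=2, seed=42)
    session, gt = simulate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def small_profiles(small_session):
    session, _ = small_session
    return score_session(session)


@pytest.fixture(scope="session")
def gain5_session():
    """40 units, 4 presentations/class, fixed 5x gain: strong-effect session."""
    cfg = SimConfig(n_units=40, events_per_class=4, event_gain=5.0, seed=7)
    session, gt = simulate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def gain5_profiles(gain5_session):
    session, _ = gain5_session
    return score_session(session)


@pytest.fixture(scope="session")
def tracked_bouts():
    """One minute of balanced scripted behavior with pose tracks."""
    cfg = SimConfig(seed=3)
    rng = np.random.default_rng(3)
    table, labels = simulate_tracking(cfg, duration_s=90.0, rng=rng, balanced=True)
    return table, np.asarray(labels)
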