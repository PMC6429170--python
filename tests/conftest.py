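import numpy as np
import pytest

import erpleak as el


@pytest.fixture(scope="session")
def small_session():
    """Default-strength user, 30 reps per tag, blinks on (180 epochs)."""
    profile = el.make_user_profile(seed=7)
    cfg = el.SessionConfig(reps_per_tag=30, seed=123)
    return profile, el.simulate_session(profile, cfg)


@pytest.fixture(scope="session")
def clean_session():
    """No blinks, 24 reps per tag: every epoch survives rejection."""
    profile = el.make_user_profile(seed=3)
    cfg = el.SessionConfig(reps_per_tag=24, blink_rate=0.0, seed=11)
    return profile, el.simulate_session(profile, cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Three users, 24 reps per tag, moderate spread."""
    cfg = el.SessionConfig(reps_per_tag=24, seed=0)
    return el.simulate_cohort(3, seed=21, spread=1.0, config=cfg)


@pytest.fixture(scope="session")
def reduced_small(small_session):
    """Average-PCA scores + binary labels of the small session."""
    _, session = small_session
    obs = el.preprocess_session(session)
    red = el.reduce_observations(obs, variant="average", n_d=5)
    return red, el.pin_labels(red.tags)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
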