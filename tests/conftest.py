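import numpy as np
import pytest

from raphetag.presets import paper_like_cohort, simulate_tagging_session
from raphetag.simulate import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tagging_session():
    """Light-stimulation epoch with 10 units (3 tagged)."""
    return simulate_tagging_session(7, n_units=10, n_tagged=3)


@pytest.fixture(scope="session")
def task_session():
    """Small full task session: 2 units, 60 trials, reward vs punishment."""
    cfg = paper_like_cohort(11, n_units=2, n_tagged=1, n_trials=60)
    return generate_cohort(cfg)[0]
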