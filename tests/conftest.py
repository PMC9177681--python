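import numpy as np
import pytest

from predcontrol import DesignSpec, TrialSequence, generate_design


@pytest.fixture(scope="session")
def default_design():
    return DesignSpec(ordering_seed=7)


@pytest.fixture(scope="session")
def default_skeleton(default_design):
    return generate_design(default_design)


@pytest.fixture(scope="session")
def small_design():
    """6 items x 4 reps over 2 sessions = 24 trials; quick to fit."""
    return DesignSpec(n_items=6, reps_per_item=4, n_sessions=2,
                      ordering_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def binary_sequence(default_skeleton):
    """A fixed stochastic rating sequence over the default design."""
    rng = np.random.default_rng(99)
    y = (rng.random(len(default_skeleton)) < 0.4).astype(int)
    return TrialSequence(item_id=default_skeleton.item_id,
                         session=default_skeleton.session,
                         outcomes=y)
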