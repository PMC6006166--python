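import numpy as np
import pytest

from pefmri.task import generate_schedule
from pefmri.rl import QParams, simulate_agent


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_schedule():
    return generate_schedule(30, seed=7)


@pytest.fixture(scope="session")
def typical_behaviour():
    """One simulated subject with the default-ish agent parameters."""
    sched = generate_schedule(30, seed=11)
    rng = np.random.default_rng(99)
    return simulate_agent(QParams(alpha=0.3, beta=3.0), sched, rng)
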