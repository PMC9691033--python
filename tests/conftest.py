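import numpy as np
import pytest

from ruleswitch.config import PARAMETER_PRESETS
from ruleswitch.synthetic import SimulationConfig, generate_fixture, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20230914)


@pytest.fixture(scope="session")
def perfect_fixture():
    return generate_fixture("perfect_agent", seed=5)


@pytest.fixture(scope="session")
def axis1_fixture():
    return generate_fixture("axis1_only", seed=6)


@pytest.fixture(scope="session")
def mini_fixture():
    return generate_fixture("three_block_mini", seed=7)


@pytest.fixture(scope="session")
def io_cohort():
    """Ten simulated days of the ideal observer at the monkey-S fitted means."""
    config = SimulationConfig(model="IO", params=PARAMETER_PRESETS["monkeyS_io"], seed=301)
    return simulate_cohort(config, 10)


@pytest.fixture(scope="session")
def hql_cohort():
    """Ten simulated days of the hybrid learner at the monkey-S fitted means."""
    config = SimulationConfig(model="HQL", params=PARAMETER_PRESETS["monkeyS_hql"], seed=302)
    return simulate_cohort(config, 10)


@pytest.fixture(scope="session")
def ql_cohort():
    """Ten simulated days of the incremental learner at the monkey-S fitted means."""
    config = SimulationConfig(model="QL", params=PARAMETER_PRESETS["monkeyS_ql"], seed=303)
    return simulate_cohort(config, 10)
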