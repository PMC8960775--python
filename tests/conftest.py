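import numpy as np
import pytest

from autrain.agents import AgentSpec, simulate_session
from autrain.io import to_frame
from autrain.schedule import build_aut_schedule
from autrain.tasks import detection_task, three_choice_task, two_choice_task


@pytest.fixture(scope="session")
def schedule():
    return build_aut_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def task2():
    return two_choice_task()


@pytest.fixture(scope="session")
def task3():
    return three_choice_task()


@pytest.fixture(scope="session")
def det_task():
    return detection_task()


@pytest.fixture(scope="session")
def random_2ac_frame(task2):
    """2000-trial random-agent 2AC session as a log DataFrame."""
    records = simulate_session(task2, AgentSpec(policy="random", seed=7), 2000, seed=7)
    return to_frame(records)
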