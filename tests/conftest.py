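import numpy as np
import pytest

from pstlearn.qlearning import ModelParams, simulate_agent
from pstlearn.task import TaskConfig


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def typical_params():
    """Learning parameters in the range typically fitted for this task."""
    return ModelParams.approach_avoid(0.3, 0.1, 0.25)


@pytest.fixture(scope="session")
def agent_log(default_config, typical_params):
    """One simulated agent with a fixed-length six-block training phase."""
    cfg = default_config.replace(max_blocks=6)
    return simulate_agent(
        typical_params,
        cfg,
        np.random.default_rng(123),
        stop_at_criterion=False,
        participant_id="fixture_agent",
    )
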