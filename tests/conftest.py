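import numpy as np
import pytest

from uncstress.learning import HGFParams, trajectory_for_subject
from uncstress.task import TaskConfig, generate_schedule

# A small but structurally valid session used by tests that do not need the
# full 320-trial default (keeps physiology tests fast).
SMALL_CONFIG = TaskConfig(
    n_trials=64,
    n_blocks=2,
    block_len_min=26,
    block_len_max=38,
    probability_classes=((0.9, 1), (0.3, 1)),
    n_ratings=10,
)


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(TaskConfig(), seed=1)


@pytest.fixture(scope="session")
def small_schedule():
    return generate_schedule(SMALL_CONFIG, seed=1)


@pytest.fixture(scope="session")
def default_trajectory(default_schedule):
    return trajectory_for_subject(
        "hgf", {"omega": -3.0, "theta": 0.1},
        default_schedule.outcome, default_schedule.stimulus,
    )


@pytest.fixture(scope="session")
def small_trajectory(small_schedule):
    return trajectory_for_subject(
        "hgf", {"omega": -3.0, "theta": 0.1},
        small_schedule.outcome, small_schedule.stimulus,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
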