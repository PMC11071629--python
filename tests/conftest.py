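import numpy as np
import pytest

from seqchoice.task import BehaviorPolicy, TaskConfig, default_archetypes


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def policy_c():
    return BehaviorPolicy.from_reference("C")


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def small_session(task, policy_c, archetypes):
    """A modest noiseless choice session shared by read-only tests."""
    from seqchoice.synth import simulate_choice_session

    return simulate_choice_session(
        task, policy_c, archetypes["cluster2_bad"], n_trials=40, seed=123,
        noise_sd=0.0,
    )


def target_xy(task, angle_deg):
    return (
        task.target_eccentricity * np.cos(np.radians(angle_deg)),
        task.target_eccentricity * np.sin(np.radians(angle_deg)),
    )
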