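import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session", autouse=True)
def _compiled_kernels():
    from pavbias._kernels import warm_up

    warm_up()


@pytest.fixture(scope="session")
def vl_agent():
    """One plausible valenced-learning agent (natural space)."""
    return {"rho": 4.0, "lam_app": 0.2, "lam_av": 0.25, "b_go": 0.6,
            "b_pav": 0.3, "xi": 0.06}


@pytest.fixture(scope="session")
def vl_session(vl_agent):
    from pavbias import make_task_schedule, simulate_session

    return simulate_session(vl_agent, "valenced_learning",
                            make_task_schedule(7), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """12-agent single-wave cohort from the default population."""
    from pavbias import PopulationSpec, simulate_cohort

    cohorts, params = simulate_cohort(PopulationSpec(n=12, seed=21))
    return cohorts[0], params[0]


def make_scripted_session(pid, correct_per_condition, seed=0,
                          session="baseline"):
    """Session whose responses are Bernoulli-correct at given per-condition
    rates - bypasses the RL model for descriptive-statistics tests."""
    from pavbias.task import (CORRECT_ACTION, GO, NOGO, SessionData,
                              make_task_schedule)

    sched = make_task_schedule(seed)
    rng = np.random.default_rng(seed + 1)
    correct = rng.random(144) < np.asarray(correct_per_condition)[sched.condition]
    right = CORRECT_ACTION[sched.condition]
    action = np.where(correct, right, 1 - right)
    win = sched.condition < 2
    best = np.where(win, 1, 0)
    worst = np.where(win, 0, -1)
    hit = (action == right) == sched.validity_draw
    outcome = np.where(hit, best, worst)
    return SessionData(
        participant_id=pid, session=session, stimulus=sched.stimulus.copy(),
        condition=sched.condition.copy(), action=action.astype(np.int64),
        outcome=outcome.astype(np.int64),
        feedback_valid=(outcome == best))
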