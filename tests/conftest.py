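import numpy as np
import pytest

from sfgpi import simulate, task


@pytest.fixture(scope="session")
def features():
    return task.default_features()


@pytest.fixture(scope="session")
def tasks_all():
    return task.default_tasks()


@pytest.fixture(scope="session")
def rm_full():
    return task.full_reward_matrix()


@pytest.fixture(scope="session")
def schedules6():
    """A full 6-block experiment (the study's structure)."""
    return task.generate_experiment(6, seed=123)


@pytest.fixture(scope="session")
def schedules2():
    """Two blocks (4 runs): enough for leave-one-run-out decoding tests."""
    return task.generate_experiment(4, seed=123)[:2]


@pytest.fixture(scope="session")
def sfgpi_cohort(schedules6):
    """Noiseless single-strategy cohort reusing training policies."""
    cfg = simulate.CohortConfig(
        n_participants=4, agent_mix={"SFGPI": 1.0}, exploration_trials=0, seed=7
    )
    return simulate.simulate_cohort(cfg, schedules6)


def make_participant_runs(
    schedules,
    neural_cfg,
    behavioral=None,
    participant=1,
    rng=None,
):
    """Simulate all runs of one participant with shared city patterns."""
    if behavioral is None:
        # keep the default exploration window: early training choices sample
        # all four cities, so every decoder class has trials
        cfg = simulate.CohortConfig(
            n_participants=participant,
            agent_mix={"SFGPI": 1.0},
            seed=11,
        )
        behavioral = simulate.simulate_cohort(cfg, schedules)
    rng = rng or np.random.default_rng(neural_cfg.seed)
    runs, patterns, feature_patterns = [], None, None
    for schedule in schedules:
        choices = simulate.participant_choices(
            behavioral, participant, schedule.config.block_index
        )
        block_runs, truth = simulate.simulate_roi_runs(
            schedule,
            choices,
            neural_cfg,
            patterns=patterns,
            feature_patterns=feature_patterns,
            rng=rng,
        )
        patterns = truth["patterns"]
        feature_patterns = truth["feature_patterns"]
        runs.extend(block_runs)
    return runs, behavioral, {"patterns": patterns, "feature_patterns": feature_patterns}
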