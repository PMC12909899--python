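import numpy as np
import pandas as pd
import pytest

from foragebold.agents import AgentParams, CohortSpec, make_cohort, simulate_cohort_behaviour
from foragebold.behavior import code_trials
from foragebold.task import default_config


@pytest.fixture(scope="session")
def task_config():
    return default_config(rng_seed=0)


def make_event_table(values_decisions, env="poor", subject="s01"):
    """Tiny hand-built event table from (option value, decision) pairs."""
    labels = {5.0: "low", 10.0: "mid", 50.0: "high"}
    n = len(values_decisions)
    values = [float(v) for v, _ in values_decisions]
    decisions = [int(d) for _, d in values_decisions]
    onsets = 9.0 * np.arange(n)
    return pd.DataFrame({
        "subject": subject, "round": 1, "block": 1, "env": env,
        "trial": np.arange(1, n + 1), "trial_in_block": np.arange(1, n + 1),
        "onset_s": onsets, "go_cue_onset_s": onsets + 4.5,
        "feedback_onset_s": [o + 9.0 if d else np.nan
                             for o, d in zip(onsets, decisions)],
        "option_label": [labels[v] for v in values],
        "option_value": values, "decision": decisions,
        "reward": [v * d for v, d in zip(values, decisions)],
    })


@pytest.fixture()
def worked_example():
    """The six-trial sequence used to pin down the switch taxonomy."""
    return make_event_table(
        [(10, 1), (5, 0), (10, 0), (10, 0), (50, 1), (10, 1)], env="poor")


@pytest.fixture(scope="session")
def small_cohort_coded(task_config):
    """A small adaptive cohort with full sessions, coded; shared read-only."""
    cohort = make_cohort(
        CohortSpec(n_subjects=6, sd_beta_env=0.5, sd_beta_prev_policy=0.3,
                   rng_seed=11),
        AgentParams(beta0=-0.5, beta_value=0.15, beta_env=-1.0,
                    beta_prev_policy=0.8))
    trials = simulate_cohort_behaviour(task_config, cohort,
                                       np.random.default_rng(11))
    return code_trials(trials)


@pytest.fixture(scope="session")
def one_subject_events(small_cohort_coded):
    return (small_cohort_coded[small_cohort_coded["subject"] == "s01"]
            .reset_index(drop=True))
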