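"""Trial-level policy coding and the behavioural mixed-logit registry.

Derives, from a raw event table, the per-trial codes on which the behavioural
analyses run: the previous policy (the subject's decision at the last
encounter with the same option), the previous action (the decision on the
immediately preceding trial regardless of option), policy- and action-switch
indicators, the switch direction, its congruence with the environment
(pursue-switches are environment-appropriate in poor blocks, reject-switches
in rich blocks), and the sliding-window average offered value.  Lookbacks
never cross subject boundaries and by default reset at round boundaries
(blocks within a round share continuous experience; rounds are separated by
breaks); the offered-value window crosses block boundaries within a round.

The registry maps each behavioural regression to its response, fixed and
random terms, and trial subset, and fits it with the Laplace mixed logit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mixedlogit import FitResult, fit_mixed_logit

__all__ = [
    "code_trials",
    "run_behaviour_glms",
    "delta_pursue_rate",
    "BEHAVIOUR_GLM_REGISTRY",
]

logger = logging.getLogger(__name__)

CODED_COLUMNS = (
    "prev_policy", "prev_action", "policy_switch", "action_switch",
    "switch_direction", "congruence", "avg_value", "env_code",
    "pursue_switch", "reject_switch",
)


def _validate_sorted(trials: pd.DataFrame) -> None:
    for subject, g in trials.groupby("subject", sort=False):
        idx = g["trial"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"duplicated trial indices for subject {subject!r}")
        if np.any(np.diff(idx) <= 0):
            raise ValueError(
                f"trials must be sorted by subject then trial index "
                f"(subject {subject!r} is out of order)")


def code_trials(trials: pd.DataFrame, learning_window: int = 5,
                reset_at_round: bool = True) -> pd.DataFrame:
    """Return a copy of the event table with all derived policy codes.

    Idempotent: recoding a coded table recomputes identical columns.
    ``reset_at_round=False`` lets lookbacks cross round boundaries (they never
    cross subjects).
    """
    _validate_sorted(trials)
    df = trials.reset_index(drop=True).copy()
    n = len(df)
    prev_policy = np.full(n, np.nan)
    prev_action = np.full(n, np.nan)
    avg_value = np.full(n, np.nan)

    group_cols = ["subject", "round"] if reset_at_round else ["subject"]
    for _, g in df.groupby(group_cols, sort=False):
        last_by_option: dict = {}
        last_decision = None
        values: list = []
        for pos, row in zip(g.index, g.itertuples(index=False)):
            lab = row.option_label
            if lab in last_by_option:
                prev_policy[pos] = 0.5 if last_by_option[lab] == 1 else -0.5
            if last_decision is not None:
                prev_action[pos] = 0.5 if last_decision == 1 else -0.5
            if len(values) >= learning_window:
                avg_value[pos] = float(np.mean(values[-learning_window:]))
            last_by_option[lab] = row.decision
            last_decision = row.decision
            values.append(row.option_value)

    decision = df["decision"].to_numpy(dtype=float)
    policy_switch = np.where(np.isnan(prev_policy), np.nan,
                             (decision != (prev_policy > 0)).astype(float))
    action_switch = np.where(np.isnan(prev_action), np.nan,
                             (decision != (prev_action > 0)).astype(float))

    direction = np.where(
        (policy_switch == 1) & (decision == 1), "pursue-switch",
        np.where((policy_switch == 1) & (decision == 0), "reject-switch", "none"))

    env_code = (df["env"] == "rich").astype(float).to_numpy()
    congruence = np.full(n, None, dtype=object)
    switched = policy_switch == 1
    pursue_sw = switched & (decision == 1)
    reject_sw = switched & (decision == 0)
    congruence[pursue_sw & (env_code == 0)] = "congruent"
    congruence[pursue_sw & (env_code == 1)] = "incongruent"
    congruence[reject_sw & (env_code == 1)] = "congruent"
    congruence[reject_sw & (env_code == 0)] = "incongruent"

    # conditional switch-direction responses: a pursue-switch is only possible
    # when the previous policy was reject, and vice versa
    pursue_switch = np.where(prev_policy == -0.5, (decision == 1).astype(float), np.nan)
    reject_switch = np.where(prev_policy == 0.5, (decision == 0).astype(float), np.nan)

    df["prev_policy"] = prev_policy
    df["prev_action"] = prev_action
    df["policy_switch"] = policy_switch
    df["action_switch"] = action_switch
    df["switch_direction"] = direction
    df["congruence"] = congruence
    df["avg_value"] = avg_value
    df["env_code"] = env_code
    df["pursue_switch"] = pursue_switch
    df["reject_switch"] = reject_switch

    # standardised covariates used by the regression registries
    v = df["option_value"].to_numpy(dtype=float)
    df["value_z"] = (v - v.mean()) / v.std() if v.std() > 0 else 0.0
    df["avg_value_c"] = df["avg_value"] - df["avg_value"].mean()
    for src, dst in [("trial", "trial_z"), ("trial_in_block", "tib_z")]:
        df[dst] = df.groupby("subject")[src].transform(
            lambda x: (x - x.mean()) / x.std() if x.std() > 0 else 0.0)
    df["value_env"] = df["value_z"] * df["env_code"]
    df["env_tib"] = df["env_code"] * df["tib_z"]
    return df


def _subset_option(df, option_value):
    return df[df["option_value"] == option_value]


BEHAVIOUR_GLM_REGISTRY: dict = {
    # pursue-vs-reject decision models
    "1.1a": dict(response="decision",
                 fixed=["value_z", "env_code", "trial_z", "value_env"],
                 random=["1", "value_env"], per_option=False, env=None),
    "1.1b": dict(response="decision", fixed=["env_code"],
                 random=["1", "env_code"], per_option=True, env=None),
    "1.2": dict(response="decision", fixed=["env_code", "tib_z", "env_tib"],
                random=["1"], per_option=True, env=None),
    "1.3": dict(response="decision", fixed=["avg_value_c", "trial_z"],
                random=["1", "avg_value_c"], per_option=True, env=None),
    # policy persistence and option specificity
    "2.1": dict(response="decision", fixed=["value_z", "prev_policy", "trial_z"],
                random=["1", "value_z", "prev_policy"], per_option=False, env=None),
    "2.2": dict(response="decision", fixed=["value_z", "prev_action", "trial_z"],
                random=["1", "prev_action"], per_option=False, env=None),
    # policy-switch models
    "2.3": dict(response="policy_switch", fixed=["value_z", "tib_z"],
                random=["1", "value_z", "tib_z"], per_option=False, env=None),
    "2.4a": dict(response="policy_switch", fixed=["prev_policy"],
                 random=["1", "prev_policy"], per_option=True, env="poor"),
    "2.4b": dict(response="policy_switch", fixed=["prev_policy"],
                 random=["1", "prev_policy"], per_option=True, env="rich"),
    "2.5a": dict(response="pursue_switch", fixed=["env_code"],
                 random=["1", "env_code"], per_option=True, env=None),
    "2.5b": dict(response="reject_switch", fixed=["env_code"],
                 random=["1", "env_code"], per_option=True, env=None),
    "2.6a": dict(response="pursue_switch", fixed=["avg_value_c"],
                 random=["1", "avg_value_c"], per_option=True, env=None),
    "2.6b": dict(response="reject_switch", fixed=["avg_value_c"],
                 random=["1", "avg_value_c"], per_option=True, env=None),
}


def run_behaviour_glms(data: pd.DataFrame, glm_id: str,
                       option_value: float = 10.0) -> FitResult:
    """Fit one registered behavioural regression on a coded trial table.

    Option-specific models are fit on the trials of ``option_value`` (the mid
    option by default, as in the headline analyses); environment-restricted
    models additionally subset to the registered block type.
    """
    if glm_id not in BEHAVIOUR_GLM_REGISTRY:
        raise KeyError(
            f"unknown glm_id {glm_id!r}; registered: "
            f"{sorted(BEHAVIOUR_GLM_REGISTRY)}")
    spec = BEHAVIOUR_GLM_REGISTRY[glm_id]
    missing = [c for c in CODED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"table is not coded (missing {missing}); "
                         "run code_trials first")
    df = data
    if spec["per_option"]:
        df = _subset_option(df, option_value)
    if spec["env"] is not None:
        df = df[df["env"] == spec["env"]]
    fit = fit_mixed_logit(df, spec["response"], spec["fixed"], spec["random"])
    fit.meta["glm_id"] = glm_id
    return fit


def delta_pursue_rate(data: pd.DataFrame, option_value: float = 10.0) -> pd.Series:
    """Per-subject pursue-rate difference (poor - rich) for the mid option.

    Positive values mark environment-sensitive subjects.  Subjects missing
    mid-option trials in either environment are excluded with a warning.
    """
    mid = data[data["option_value"] == option_value]
    rates = mid.groupby(["subject", "env"])["decision"].mean().unstack("env")
    complete = rates.dropna(subset=["poor", "rich"])
    dropped = sorted(set(rates.index) - set(complete.index))
    if dropped:
        logger.warning("delta_pursue_rate: excluding subjects missing an "
                       "environment: %s", dropped)
    delta = complete["poor"] - complete["rich"]
    delta.name = "delta_pursue_rate"
    return delta
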