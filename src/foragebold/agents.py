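"""Synthetic choosers with known, planted decision weights.

Each agent decides pursue-vs-reject through a logistic utility over the offer
value, an environment term gated to the mid option, a persistence term (its
own decision at the last same-option encounter), and a sliding-window average
of recently offered values, mixed with a lapse probability.  Cohorts carry
Gaussian between-subject variation around mean weights, so the behavioural
regression suite can be validated by recovering the planted coefficients.

The utility form is a generative stand-in chosen so that each behavioural
regression's target coefficient is recoverable on simulated cohorts; it is not
a model of human participants.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .task import OPTION_LABELS, Encounter, TaskConfig, TrialRecord, simulate_session

__all__ = [
    "AgentParams",
    "CohortSpec",
    "agent_decision_prob",
    "make_cohort",
    "make_agent_decider",
    "simulate_cohort_behaviour",
    "expected_offer_value",
    "trials_to_frame",
]

VALUE_CENTER = 10.0  # offer value is centred at the mid option's value
PREV_POLICY_CODES = {1: 0.5, 0: -0.5}  # last same-option decision, +-0.5


@dataclass(frozen=True)
class AgentParams:
    """Logit-scale decision weights for one synthetic subject."""

    beta0: float = 0.0
    beta_value: float = 0.0          # per point of (offer value - 10)
    beta_env: float = 0.0            # rich=1/poor=0 indicator, mid option only
    beta_prev_policy: float = 0.0    # last same-option decision, coded +-0.5
    beta_avg_value: float = 0.0      # per point of centred 5-trial average value
    learning_window: int = 5
    lapse: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.5):
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.learning_window < 1:
            raise ValueError("learning_window must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and Gaussian between-subject SDs for each agent weight."""

    n_subjects: int = 27
    sd_beta0: float = 0.0
    sd_beta_value: float = 0.0
    sd_beta_env: float = 0.0
    sd_beta_prev_policy: float = 0.0
    sd_beta_avg_value: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("sd_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


def expected_offer_value(config: TaskConfig) -> float:
    """Session-wide expected offer value (equal time in rich and poor)."""
    means = [sum(env.prob(lab) * config.value_of(lab) for lab in OPTION_LABELS)
             for env in config.environments]
    return float(np.mean(means))


def agent_decision_prob(params: AgentParams, offer_label: str, offer_value: float,
                        env_code: float, prev_policy: float | None,
                        avg_value: float | None, avg_value_center: float) -> float:
    """Pursue probability for one encounter.

    ``prev_policy`` is the +-0.5-coded decision at the last same-option
    encounter (None if that option has not been met in the current round);
    ``avg_value`` is the mean offered value over the previous
    ``learning_window`` trials of the round (None with insufficient history).
    Terms with an undefined covariate contribute zero; the lapse mixes in a
    uniform-random decision.
    """
    eta = params.beta0 + params.beta_value * (offer_value - VALUE_CENTER)
    if offer_label == "mid":
        eta += params.beta_env * env_code
    if prev_policy is not None:
        eta += params.beta_prev_policy * prev_policy
    if avg_value is not None:
        eta += params.beta_avg_value * (avg_value - avg_value_center)
    p = 1.0 / (1.0 + np.exp(-eta))
    return float((1.0 - params.lapse) * p + params.lapse / 2.0)


def make_cohort(spec: CohortSpec, mean_params: AgentParams) -> list[AgentParams]:
    """Draw per-subject weights as mean + Gaussian deviations with the cohort SDs."""
    rng = np.random.default_rng(spec.rng_seed)
    cohort = []
    for _ in range(spec.n_subjects):
        cohort.append(replace(
            mean_params,
            beta0=mean_params.beta0 + spec.sd_beta0 * rng.standard_normal(),
            beta_value=mean_params.beta_value + spec.sd_beta_value * rng.standard_normal(),
            beta_env=mean_params.beta_env + spec.sd_beta_env * rng.standard_normal(),
            beta_prev_policy=(mean_params.beta_prev_policy
                              + spec.sd_beta_prev_policy * rng.standard_normal()),
            beta_avg_value=(mean_params.beta_avg_value
                            + spec.sd_beta_avg_value * rng.standard_normal()),
        ))
    return cohort


def make_agent_decider(params: AgentParams, config: TaskConfig,
                       rng: np.random.Generator):
    """Stateful decision callback for :func:`simulate_session`.

    Tracks the agent's last decision per option and the offered-value window,
    both resetting at round boundaries (blocks within a round share continuous
    experience; rounds are separated by breaks), matching the analysis
    module's trial-coding conventions.
    """
    avg_center = expected_offer_value(config)
    state = {"round": None, "last": {}, "values": []}

    def decide(enc: Encounter, history: list[TrialRecord]) -> int:
        if enc.round_index != state["round"]:
            state["round"] = enc.round_index
            state["last"] = {}
            state["values"] = []
        prev = state["last"].get(enc.option_label)
        prev_coded = PREV_POLICY_CODES[prev] if prev is not None else None
        w = params.learning_window
        avg = (float(np.mean(state["values"][-w:]))
               if len(state["values"]) >= w else None)
        env_code = 1.0 if enc.env_type == "rich" else 0.0
        p = agent_decision_prob(params, enc.option_label, enc.option_value,
                                env_code, prev_coded, avg, avg_center)
        decision = int(rng.random() < p)
        state["last"][enc.option_label] = decision
        state["values"].append(enc.option_value)
        return decision

    return decide


def simulate_cohort_behaviour(config: TaskConfig, cohort: list[AgentParams],
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate an independent randomised session per agent; concatenated table."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    frames = []
    for i, params in enumerate(cohort):
        subject_id = f"s{i + 1:02d}"
        decide = make_agent_decider(params, config, rng)
        records = simulate_session(config, decide, rng, subject_id=subject_id)
        frames.append(trials_to_frame(records))
    return pd.concat(frames, ignore_index=True)


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Convert TrialRecords to the canonical event table."""
    return pd.DataFrame({
        "subject": [r.subject_id for r in records],
        "round": [r.round_index for r in records],
        "block": [r.block_index for r in records],
        "env": [r.env_type for r in records],
        "trial": [r.trial_index for r in records],
        "trial_in_block": [r.trial_in_block for r in records],
        "onset_s": [r.onset_s for r in records],
        "go_cue_onset_s": [r.go_cue_onset_s for r in records],
        "feedback_onset_s": [np.nan if r.feedback_onset_s is None else r.feedback_onset_s
                             for r in records],
        "option_label": [r.option_label for r in records],
        "option_value": [r.option_value for r in records],
        "decision": [r.decision for r in records],
        "reward": [r.reward for r in records],
    })
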