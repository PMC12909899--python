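"""Generative model of the sequential pursue/reject foraging task.

The task presents a stream of reward offers (5, 10 or 50 points) drawn from
environment-specific frequency distributions ("rich" blocks over-represent the
50-point offer, "poor" blocks the 5-point offer).  Pursuing an offer costs the
time of one future encounter, so whether an offer is worth pursuing depends on
the opportunity cost implied by the environment's reward rate.  This module
holds the task's generative specification, the session simulator, and the
renewal-theoretic optimality engine (reward rates per option-policy, the
optimal pursue-set, and the expected-earnings surface over mid-option pursuit
rates).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Encounter",
    "RewardOption",
    "TruncExpSpec",
    "EnvironmentSpec",
    "TimingSpec",
    "TaskConfig",
    "Policy",
    "TrialRecord",
    "sample_truncated_exponential",
    "truncated_exponential_rate",
    "draw_offer",
    "simulate_session",
    "reward_rate",
    "optimal_policy",
    "earnings_surface",
    "default_config",
]

OPTION_LABELS = ("low", "mid", "high")


@dataclass(frozen=True)
class RewardOption:
    """A reward offer type with a fixed, known point value."""

    label: str
    value: float

    def __post_init__(self) -> None:
        if self.label not in OPTION_LABELS:
            raise ValueError(f"label must be one of {OPTION_LABELS}, got {self.label!r}")
        if self.value <= 0:
            raise ValueError("option value must be strictly positive")


@dataclass(frozen=True)
class TruncExpSpec:
    """Truncated-exponential delay: target mean mu on support [lo, hi] seconds."""

    mu: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mu <= self.hi):
            raise ValueError(f"need lo <= mu <= hi, got {self}")
        if self.lo < self.hi and not (self.lo < self.mu < self.hi):
            raise ValueError("mu must lie strictly inside (lo, hi) unless lo == hi")


@dataclass(frozen=True)
class EnvironmentSpec:
    """Offer-frequency distribution for one environment type."""

    env_type: str  # "rich" | "poor"
    offer_probs: dict  # option label -> probability

    def __post_init__(self) -> None:
        if self.env_type not in ("rich", "poor"):
            raise ValueError(f"env_type must be 'rich' or 'poor', got {self.env_type!r}")
        probs = dict(self.offer_probs)
        if set(probs) != set(OPTION_LABELS):
            raise ValueError(f"offer_probs must have keys {OPTION_LABELS}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("offer probabilities must be nonnegative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"offer probabilities must sum to 1, got {total}")

    def prob(self, label: str) -> float:
        return self.offer_probs[label]


@dataclass(frozen=True)
class TimingSpec:
    iti: TruncExpSpec = TruncExpSpec(4.5, 3.5, 5.5)
    opportunity_delay: TruncExpSpec = TruncExpSpec(4.5, 3.5, 5.5)
    action_outcome_delay: TruncExpSpec = TruncExpSpec(4.5, 3.5, 5.5)
    feedback_delay: TruncExpSpec = TruncExpSpec(4.5, 3.5, 5.5)
    response_window: float = 1.0
    block_duration: float = 270.0
    rounds: int = 5
    blocks_per_round: int = 2
    inter_round_break: float = 60.0

    def __post_init__(self) -> None:
        if self.response_window <= 0:
            raise ValueError("response_window must be > 0")
        if self.block_duration <= 0:
            raise ValueError("block_duration must be > 0")

    @property
    def slot_seconds(self) -> float:
        """Expected duration of one encounter slot (ITI + opportunity delay)."""
        return self.iti.mu + self.opportunity_delay.mu

    @property
    def pursuit_extra_seconds(self) -> float:
        """Expected extra time a pursuit adds (action-outcome + feedback delays)."""
        return self.action_outcome_delay.mu + self.feedback_delay.mu


@dataclass(frozen=True)
class TaskConfig:
    options: tuple = (
        RewardOption("low", 5.0),
        RewardOption("mid", 10.0),
        RewardOption("high", 50.0),
    )
    environments: tuple = ()
    timing: TimingSpec = TimingSpec()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.options) != 3:
            raise ValueError("exactly three reward options required")
        values = [o.value for o in self.options]
        if not (values[0] < values[1] < values[2]):
            raise ValueError("option values must be strictly ordered low < mid < high")
        if len(self.environments) != 2:
            raise ValueError("exactly two environments (rich + poor) required")
        types = sorted(e.env_type for e in self.environments)
        if types != ["poor", "rich"]:
            raise ValueError("environments must be one rich and one poor")
        p_mid = [e.prob("mid") for e in self.environments]
        if abs(p_mid[0] - p_mid[1]) > 1e-12:
            raise ValueError("mid-option frequency must be equal across environments")

    def option(self, label: str) -> RewardOption:
        for o in self.options:
            if o.label == label:
                return o
        raise KeyError(label)

    def environment(self, env_type: str) -> EnvironmentSpec:
        for e in self.environments:
            if e.env_type == env_type:
                return e
        raise KeyError(env_type)

    def value_of(self, label: str) -> float:
        return self.option(label).value


def default_config(rng_seed: int = 0, verbatim_probs: bool = False) -> TaskConfig:
    """Default task configuration.

    Offer frequencies default to exact sixths (1/6, 1/3, 1/2), which round to
    the task's nominal 0.16/0.33/0.50 and sum to one.  ``verbatim_probs``
    instead renormalises the nominal values (0.16/0.33/0.50, sum 0.99).
    """
    if verbatim_probs:
        raw_rich = {"low": 0.16, "mid": 0.33, "high": 0.50}
        raw_poor = {"low": 0.50, "mid": 0.33, "high": 0.16}
        s_r, s_p = sum(raw_rich.values()), sum(raw_poor.values())
        rich = {k: v / s_r for k, v in raw_rich.items()}
        poor = {k: v / s_p for k, v in raw_poor.items()}
    else:
        rich = {"low": 1 / 6, "mid": 1 / 3, "high": 1 / 2}
        poor = {"low": 1 / 2, "mid": 1 / 3, "high": 1 / 6}
    return TaskConfig(
        environments=(
            EnvironmentSpec("rich", rich),
            EnvironmentSpec("poor", poor),
        ),
        rng_seed=rng_seed,
    )


@dataclass(frozen=True)
class Policy:
    """Option-specific pursue probabilities; deterministic policies are vertices."""

    pursue_probs: dict  # option label -> probability in [0, 1]

    def __post_init__(self) -> None:
        if set(self.pursue_probs) != set(OPTION_LABELS):
            raise ValueError(f"pursue_probs must have keys {OPTION_LABELS}")
        for p in self.pursue_probs.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("pursue probabilities must lie in [0, 1]")

    @classmethod
    def from_set(cls, pursue_set) -> "Policy":
        pursue_set = frozenset(pursue_set)
        return cls({lab: 1.0 if lab in pursue_set else 0.0 for lab in OPTION_LABELS})

    @property
    def pursue_set(self) -> frozenset:
        return frozenset(lab for lab, p in self.pursue_probs.items() if p == 1.0)

    def prob(self, label: str) -> float:
        return self.pursue_probs[label]


class Encounter(NamedTuple):
    """The offer presented to a decision callback, with its task context."""

    option_label: str
    option_value: float
    env_type: str
    round_index: int
    block_index: int
    trial_in_block: int


@dataclass
class TrialRecord:
    subject_id: str
    round_index: int
    block_index: int  # 1-based across the session
    env_type: str
    trial_index: int  # 1-based across the session
    trial_in_block: int
    onset_s: float  # offer onset from session start
    go_cue_onset_s: float
    feedback_onset_s: float | None  # None when rejected
    option_label: str
    option_value: float
    decision: int  # pursue = 1, reject = 0
    reward: float


# ---------------------------------------------------------------------------
# Truncated-exponential delays
# ---------------------------------------------------------------------------

def _trunc_exp_mean(rate: float, width: float) -> float:
    """Mean (above lo) of an exponential with given rate truncated to [0, width].

    A negative rate tilts mass toward the upper bound; rate -> 0 is the uniform
    limit with mean width / 2.
    """
    x = rate * width
    if abs(x) < 1e-9:
        # series expansion around the uniform limit
        return width * (0.5 - x / 12.0)
    return 1.0 / rate - width * math.exp(-x) / (1.0 - math.exp(-x))


def truncated_exponential_rate(mu: float, lo: float, hi: float) -> float:
    """Solve (by bisection) for the rate whose truncated mean on [lo, hi] is mu."""
    key = (mu, lo, hi)
    cached = _RATE_CACHE.get(key)
    if cached is not None:
        return cached
    if not (lo <= mu <= hi):
        raise ValueError(f"infeasible mean: need {lo} <= {mu} <= {hi}")
    if hi == lo:
        return 0.0
    if not (lo < mu < hi):
        raise ValueError("mu must lie strictly inside (lo, hi) for a proper distribution")
    width = hi - lo
    target = mu - lo
    # mean is strictly decreasing in rate; bracket the root
    a, b = -1.0, 1.0
    while _trunc_exp_mean(a, width) < target:
        a *= 2.0
        if a < -1e8:
            raise ValueError(f"infeasible mean {mu} on [{lo}, {hi}]")
    while _trunc_exp_mean(b, width) > target:
        b *= 2.0
        if b > 1e8:
            raise ValueError(f"infeasible mean {mu} on [{lo}, {hi}]")
    for _ in range(200):
        m = 0.5 * (a + b)
        if _trunc_exp_mean(m, width) > target:
            a = m
        else:
            b = m
    rate = 0.5 * (a + b)
    _RATE_CACHE[key] = rate
    return rate


_RATE_CACHE: dict = {}


def sample_truncated_exponential(mu: float, lo: float, hi: float,
                                 rng: np.random.Generator,
                                 size=None):
    """Draw from the exponential truncated to [lo, hi] whose mean equals mu."""
    if hi == lo:
        if mu != lo:
            raise ValueError("degenerate interval requires mu == lo == hi")
        return lo if size is None else np.full(size, float(lo))
    rate = truncated_exponential_rate(mu, lo, hi)
    u = rng.random(size=size)
    width = hi - lo
    if abs(rate * width) < 1e-9:
        return lo + u * width
    # inverse CDF of the truncated exponential (valid for either sign of rate)
    return lo - np.log1p(-u * (1.0 - math.exp(-rate * width))) / rate


def _sample_delay(spec: TruncExpSpec, rng: np.random.Generator) -> float:
    return float(sample_truncated_exponential(spec.mu, spec.lo, spec.hi, rng))


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def draw_offer(env: EnvironmentSpec, rng: np.random.Generator) -> str:
    """Sample an offer label with the environment's frequencies."""
    labels = list(OPTION_LABELS)
    probs = [env.prob(lab) for lab in labels]
    return labels[rng.choice(len(labels), p=probs)]


def simulate_session(config: TaskConfig, decide, rng: np.random.Generator,
                     subject_id: str = "s01") -> list[TrialRecord]:
    """Simulate one full session and return its trial records.

    ``decide(encounter, history)`` maps the current offer (an :class:`Encounter`
    carrying the offer label/value and its block context) and the list of
    TrialRecords so far to a pursue (1) / reject (0) decision.  Each block runs
    trials until its clock reaches the block duration; a trial started before
    the limit runs to completion.  Rejected encounters consume ITI +
    opportunity delay; pursued encounters additionally consume the
    action-outcome and feedback delays (the opportunity cost of one future
    encounter in expectation).  The response window defines the go-cue contract
    but consumes no clock time (reaction times are not modelled).
    """
    t = config.timing
    records: list[TrialRecord] = []
    session_t = 0.0
    trial_index = 0
    block_index = 0
    for round_index in range(1, t.rounds + 1):
        if round_index > 1:
            session_t += t.inter_round_break
        env_order = ["rich", "poor"]
        rng.shuffle(env_order)
        for env_type in env_order[: t.blocks_per_round]:
            block_index += 1
            env = config.environment(env_type)
            block_t = 0.0
            trial_in_block = 0
            while block_t < t.block_duration:
                trial_index += 1
                trial_in_block += 1
                iti = _sample_delay(t.iti, rng)
                opp = _sample_delay(t.opportunity_delay, rng)
                onset = session_t + iti
                go_cue = onset + opp
                label = draw_offer(env, rng)
                option = config.option(label)
                encounter = Encounter(label, option.value, env_type,
                                      round_index, block_index, trial_in_block)
                decision = decide(encounter, records)
                if decision not in (0, 1, True, False):
                    raise ValueError(
                        f"decision callback must return 0/1, got {decision!r}")
                decision = int(decision)
                feedback_onset = None
                trial_dur = iti + opp
                if decision == 1:
                    ao = _sample_delay(t.action_outcome_delay, rng)
                    fb = _sample_delay(t.feedback_delay, rng)
                    feedback_onset = go_cue + ao
                    trial_dur += ao + fb
                records.append(TrialRecord(
                    subject_id=subject_id,
                    round_index=round_index,
                    block_index=block_index,
                    env_type=env_type,
                    trial_index=trial_index,
                    trial_in_block=trial_in_block,
                    onset_s=onset,
                    go_cue_onset_s=go_cue,
                    feedback_onset_s=feedback_onset,
                    option_label=label,
                    option_value=option.value,
                    decision=decision,
                    reward=option.value * decision,
                ))
                session_t += trial_dur
                block_t += trial_dur
    return records


# ---------------------------------------------------------------------------
# Optimality engine
# ---------------------------------------------------------------------------

def reward_rate(policy: Policy, env: EnvironmentSpec, config: TaskConfig):
    """Long-run reward rate of a policy in an environment.

    One slot is the expected encounter duration (ITI + opportunity delay);
    pursuing adds one further slot in expectation (action-outcome + feedback
    delays).  The renewal rate in points per slot is

        R(pi) = sum_v p(v) pi(v) v / (1 + sum_v p(v) pi(v)).

    Returns ``(points_per_slot, points_per_second)``.
    """
    num = sum(env.prob(lab) * policy.prob(lab) * config.value_of(lab)
              for lab in OPTION_LABELS)
    den = 1.0 + sum(env.prob(lab) * policy.prob(lab) for lab in OPTION_LABELS)
    per_slot = num / den
    return per_slot, per_slot / config.timing.slot_seconds


def optimal_policy(env: EnvironmentSpec, config: TaskConfig):
    """Best of the 8 deterministic policies; ties go to the smaller pursue-set.

    Returns ``(policy, points_per_slot)``.
    """
    best = None
    for r in range(4):
        for subset in itertools.combinations(OPTION_LABELS, r):
            pol = Policy.from_set(subset)
            rate, _ = reward_rate(pol, env, config)
            key = (-rate, len(subset), tuple(sorted(subset)))
            if best is None or key < best[0]:
                best = (key, pol, rate)
    return best[1], best[2]


def earnings_surface(config: TaskConfig, grid: np.ndarray,
                     slots_per_environment: int = 150):
    """Expected session points over mid-option pursuit rates (rich x poor).

    The background policy always rejects the low option and always pursues the
    high option; the grid varies the mid-option pursue probability in rich
    (rows) and poor (columns) blocks.  Returns ``(surface, (p_rich, p_poor))``
    where the pair is the surface argmax.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid values must lie in [0, 1]")
    rich = config.environment("rich")
    poor = config.environment("poor")

    def rate(env, p_mid):
        pol = Policy({"low": 0.0, "mid": float(p_mid), "high": 1.0})
        return reward_rate(pol, env, config)[0]

    rich_rates = np.array([rate(rich, p) for p in grid])
    poor_rates = np.array([rate(poor, p) for p in grid])
    surface = slots_per_environment * (rich_rates[:, None] + poor_rates[None, :])
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    return surface, (float(grid[i]), float(grid[j]))
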