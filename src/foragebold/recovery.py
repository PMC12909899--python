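"""Parameter-recovery and calibration studies on synthetic cohorts.

Every study here regenerates its inputs from scratch under a seed, runs the
full analysis path (simulate agents -> code trials -> fit, or simulate BOLD
-> epoch -> pointwise GLM -> LOO group test, etc.) and reports how well the
planted quantity is recovered.  The planted behavioural weights default to
the study's design-level values: a previous-policy persistence weight of 1.53
and a mid-option environment weight of -0.19 on the logit scale, with
between-subject SDs chosen to reproduce the heterogeneity implied by the
corresponding group-level standard errors at n = 27.

These functions are the shared code path for the acceptance checks and the
``scripts/acceptance.py`` entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .agents import AgentParams, CohortSpec, make_cohort, simulate_cohort_behaviour
from .behavior import code_trials, delta_pursue_rate, run_behaviour_glms
from .mixedlogit import SeparationError
from .neural import (DEFAULT_TR, CouplingSpec, GeometrySpec, HRFSpec,
                     NeuralPlantSpec, ar1_noise, build_design,
                     synthesize_roi_bold, synthesize_voxel_data)
from .roi import (epoch_grid, loo_peak_estimate, pointwise_glm, ppi_fit,
                  preprocess_roi)
from .rsa import estimate_patterns, rsa_scores
from .task import TaskConfig, default_config

__all__ = [
    "PLANTED_PREV_POLICY",
    "PLANTED_ENV",
    "RecoveryResult",
    "recover_prev_policy",
    "recover_env",
    "loo_calibration",
    "rsa_linkage",
    "ppi_recovery",
]

# Design-level planted weights (logit units) and the between-subject SDs used
# when generating recovery cohorts.  The SDs reproduce the group-level SE
# scale at n = 27: 1.4 ~= 0.28 * sqrt(27) for the persistence weight, while
# the environment weight's group SE is dominated by within-subject sampling
# noise, so a small 0.2 is used.
PLANTED_PREV_POLICY = 1.53
PREV_POLICY_SD = 1.4
PLANTED_ENV = -0.19
ENV_SD = 0.2
LAPSE = 0.05


@dataclass
class RecoveryResult:
    """Replicate-averaged recovery of one planted coefficient."""

    term: str
    planted: float
    estimates: np.ndarray
    halfwidths: np.ndarray  # Wald 95% CI half-widths per replicate
    covered: np.ndarray     # planted value inside the replicate CI?
    n_subjects: int

    @property
    def mean_estimate(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def mean_halfwidth(self) -> float:
        return float(np.mean(self.halfwidths))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.covered))

    @property
    def n_replicates(self) -> int:
        return len(self.estimates)


def _replicate_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _recover(mean_params: AgentParams, cohort_spec: CohortSpec, glm_id: str,
             term: str, planted: float, n_replicates: int, seed: int,
             config: TaskConfig | None = None) -> RecoveryResult:
    config = config or default_config()
    ests, hws, cov = [], [], []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        cohort = make_cohort(replace(cohort_spec, rng_seed=rep_seed), mean_params)
        trials = simulate_cohort_behaviour(config, cohort, rng)
        coded = code_trials(trials)
        try:
            fit = run_behaviour_glms(coded, glm_id)
        except SeparationError:  # pathological replicate; skip, keep count honest
            continue
        est = fit[term]
        hw = 1.96 * est["se"]
        ests.append(est["coef"])
        hws.append(hw)
        cov.append(abs(est["coef"] - planted) <= hw)
    return RecoveryResult(term, planted, np.array(ests), np.array(hws),
                          np.array(cov, dtype=bool), cohort_spec.n_subjects)


def recover_prev_policy(n_replicates: int = 100, n_subjects: int = 27,
                        seed: int = 0) -> RecoveryResult:
    """Recover the planted persistence weight with the GLM2.1-style model.

    Cohorts of ``n_subjects`` agents whose previous-policy weight averages
    1.53 (other context weights zero, lapse 0.05) play full task-clock
    sessions; each replicate fits the persistence mixed logit and the planted
    mean is compared with the replicate-averaged estimate and its Wald CI.
    """
    mean = AgentParams(beta_prev_policy=PLANTED_PREV_POLICY, lapse=LAPSE)
    spec = CohortSpec(n_subjects=n_subjects, sd_beta_prev_policy=PREV_POLICY_SD)
    return _recover(mean, spec, "2.1", "prev_policy", PLANTED_PREV_POLICY,
                    n_replicates, seed)


def recover_env(n_replicates: int = 100, n_subjects: int = 27,
                seed: int = 0) -> RecoveryResult:
    """Recover the planted mid-option environment weight (GLM1.1b model)."""
    mean = AgentParams(beta_env=PLANTED_ENV, lapse=LAPSE)
    spec = CohortSpec(n_subjects=n_subjects, sd_beta_env=ENV_SD)
    return _recover(mean, spec, "1.1b", "env_code", PLANTED_ENV,
                    n_replicates, seed)


# ---------------------------------------------------------------------------
# LOO peak calibration and power
# ---------------------------------------------------------------------------

# Cohort used for neural studies: environment-sensitive, persistent agents
# with moderate heterogeneity, so sessions contain realistic numbers of
# congruent policy-switch events.
NEURAL_COHORT_MEAN = AgentParams(beta0=-0.5, beta_value=0.15, beta_env=-1.0,
                                 beta_prev_policy=0.8, lapse=0.05)
NEURAL_COHORT_SPEC = CohortSpec(n_subjects=27, sd_beta0=0.3, sd_beta_env=0.8,
                                sd_beta_prev_policy=0.3)


def _simulate_neural_cohort(seed: int, n_subjects: int = 27):
    config = default_config()
    rng = np.random.default_rng(seed)
    spec = replace(NEURAL_COHORT_SPEC, n_subjects=n_subjects, rng_seed=seed)
    cohort = make_cohort(spec, NEURAL_COHORT_MEAN)
    trials = simulate_cohort_behaviour(config, cohort, rng)
    return code_trials(trials), cohort


@dataclass
class _PreparedSubject:
    events: pd.DataFrame
    n_scans: int
    sample_times: np.ndarray  # trials x epoch timepoints (clamped in session)
    trial_rows: np.ndarray
    signal: np.ndarray | None  # planted clean timecourse, or None


def _prepare_subjects(coded: pd.DataFrame, tr: float,
                      plant_amplitudes: dict | None) -> list[_PreparedSubject]:
    grid = epoch_grid(tr)
    prepared = []
    for _, ev in coded.groupby("subject", sort=False):
        ev = ev.reset_index(drop=True)
        last = float(np.nanmax(ev[["onset_s", "go_cue_onset_s",
                                   "feedback_onset_s"]].to_numpy(dtype=float)))
        n_scans = int(np.ceil((last + 24.0) / tr))
        times_end = tr * (n_scans - 1)
        onsets = ev["onset_s"].to_numpy(dtype=float)
        ok = (onsets + grid[0] >= 0) & (onsets + grid[-1] <= times_end)
        rows = np.where(ok)[0]
        sample_times = onsets[rows, None] + grid[None, :]
        signal = None
        if plant_amplitudes:
            from .neural import _event_mask
            regs = [(name, _event_mask(ev, name), None)
                    for name in plant_amplitudes]
            X, _ = build_design(ev, regs, tr, HRFSpec(), n_scans)
            signal = X @ np.array(list(plant_amplitudes.values()), dtype=float)
        prepared.append(_PreparedSubject(ev, n_scans, sample_times, rows, signal))
    return prepared


def _replicate_glm_betas(prep: list[_PreparedSubject], glm_ids: list[str],
                         tr: float, rng: np.random.Generator,
                         noise_sd: float = 1.0, ar1: float = 0.3):
    """One replicate: fresh AR(1) noise per subject, pointwise GLM betas."""
    from .roi import EpochedSignal
    grid = epoch_grid(tr)
    betas = {g: [] for g in glm_ids}
    for ps in prep:
        y = ar1_noise(ps.n_scans, noise_sd, ar1, rng)
        if ps.signal is not None:
            y = y + ps.signal * noise_sd
        y = (y - y.mean()) / y.std()
        spline = CubicSpline(tr * np.arange(ps.n_scans), y)
        data = spline(ps.sample_times)
        epochs = EpochedSignal(str(ps.events["subject"].iloc[0]), "roi",
                               ps.trial_rows, grid, data)
        for g in glm_ids:
            try:
                betas[g].append(pointwise_glm(epochs, ps.events, g))
            except ValueError:
                # subject has no events of this type (e.g. zero congruent
                # reject-switches); they cannot contribute to this regressor
                continue
    return betas


def loo_calibration(n_null: int = 1000, n_planted: int = 200,
                    n_subjects: int = 27, seed: int = 0,
                    amplitude: float = 1.0, alpha: float = 0.05) -> dict:
    """Type-I error and power of the LOO peak test on synthetic ROI data.

    Null replicates regenerate pure AR(1) noise over one cohort's fixed event
    tables and test the policy-switch regressor; planted replicates add
    event-locked responses of ``amplitude`` noise-SD units (positive at
    congruent pursue-switches, negative at congruent reject-switches) and
    test the congruent pursue and reject regressors.
    """
    coded, _ = _simulate_neural_cohort(seed, n_subjects)
    tr = DEFAULT_TR
    rng = np.random.default_rng(seed + 1)

    null_rej = 0
    prep_null = _prepare_subjects(coded, tr, None)
    for _ in range(n_null):
        b = _replicate_glm_betas(prep_null, ["4.1a"], tr, rng)
        eff = loo_peak_estimate(b["4.1a"], "policy_switch")
        null_rej += eff.p < alpha

    plant = {"congruent_pursue": amplitude, "congruent_reject": -amplitude}
    prep_plant = _prepare_subjects(coded, tr, plant)
    pursue_rej = 0
    pursue_means, reject_means = [], []
    for _ in range(n_planted):
        b = _replicate_glm_betas(prep_plant, ["4.2a", "4.2c"], tr, rng)
        ep = loo_peak_estimate(b["4.2a"], "congruent_pursue")
        er = loo_peak_estimate(b["4.2c"], "congruent_reject")
        pursue_rej += ep.p < alpha
        pursue_means.append(np.mean(ep.loo_betas))
        reject_means.append(np.mean(er.loo_betas))
    return {
        "null_rejection_rate": null_rej / n_null if n_null else np.nan,
        "planted_power": pursue_rej / n_planted if n_planted else np.nan,
        "mean_pursue_peak": float(np.mean(pursue_means)) if n_planted else np.nan,
        "mean_reject_peak": float(np.mean(reject_means)) if n_planted else np.nan,
        "n_null": n_null, "n_planted": n_planted, "n_subjects": n_subjects,
    }


# ---------------------------------------------------------------------------
# RSA brain-behaviour linkage
# ---------------------------------------------------------------------------

KAPPA_PER_ADAPTIVITY = 0.5  # kappa = 0.5 * max(0, -beta_env), clipped to [0, 1]
RSA_GEOMETRY = GeometrySpec(n_voxels=40, pattern_noise_sd=1.0, amplitude=2.0)


def rsa_linkage(n_replicates: int = 100, n_subjects: int = 27, seed: int = 0,
                shuffle: bool = False, alpha: float = 0.05) -> dict:
    """End-to-end recovery of the H2-vs-behaviour correlation.

    Each replicate simulates an adaptive cohort, assigns each subject a
    mid-pattern warp kappa proportional to their planted environment
    sensitivity, synthesises voxel data, estimates patterns, scores H2 and
    correlates it with the behavioural change score.  ``shuffle=True``
    permutes kappa across subjects, breaking the linkage.
    """
    sig_pos = 0
    rvals = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        coded, cohort = _simulate_neural_cohort(rep_seed, n_subjects)
        kappas = np.clip([KAPPA_PER_ADAPTIVITY * max(0.0, -p.beta_env)
                          for p in cohort], 0.0, 1.0)
        if shuffle:
            kappas = rng.permutation(kappas)
        h2 = {}
        for (subj, ev), kap in zip(coded.groupby("subject", sort=False), kappas):
            ev = ev.reset_index(drop=True)
            geom = replace(RSA_GEOMETRY, kappa=float(kap))
            vox = synthesize_voxel_data(ev, geom, rng)
            pats = estimate_patterns(vox, ev, subject=subj)
            h2[subj] = rsa_scores(pats, "cosine").h2
        delta = delta_pursue_rate(coded)
        joined = pd.DataFrame({"H2": pd.Series(h2), "delta": delta}).dropna()
        r, p = stats.pearsonr(joined["H2"], joined["delta"])
        rvals.append(r)
        sig_pos += (r > 0) and (p < alpha)
    return {"fraction_significant_positive": sig_pos / n_replicates,
            "mean_r": float(np.mean(rvals)),
            "mean_abs_r": float(np.mean(np.abs(rvals))),
            "n_replicates": n_replicates, "n_subjects": n_subjects}


# ---------------------------------------------------------------------------
# PPI recovery
# ---------------------------------------------------------------------------

PPI_GAIN_POOR = 0.5


def ppi_recovery(n_replicates: int = 100, n_subjects: int = 27, seed: int = 0,
                 env_dependent: bool = True, noise_sd: float = 1.0,
                 alpha: float = 0.05) -> dict:
    """Group-level recovery of environment-modulated seed-target coupling.

    With ``env_dependent`` the planted gain is 0.5 in poor blocks and 0 in
    rich blocks (rich coded 1, so the planted interaction is negative);
    otherwise the gain is a constant 0.25 in both, and the interaction should
    be null while the seed main effect stays positive.
    """
    gains = ((0.0, PPI_GAIN_POOR) if env_dependent else (0.25, 0.25))
    sig = 0
    coefs_all = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        coded, _ = _simulate_neural_cohort(rep_seed, n_subjects)
        coefs = []
        for _, ev in coded.groupby("subject", sort=False):
            ev = ev.reset_index(drop=True)
            plant = NeuralPlantSpec(
                amplitudes={"seed": {}, "target": {}},
                noise_sd=noise_sd, ar1=0.3,
                couplings=(CouplingSpec("seed", "target",
                                        gain_rich=gains[0], gain_poor=gains[1]),))
            tcs = synthesize_roi_bold(ev, plant, rng)
            fit = ppi_fit(preprocess_roi(tcs["target"]),
                          preprocess_roi(tcs["seed"]), ev)
            coefs.append(fit["ppi"]["coef"])
        t, p = stats.ttest_1samp(coefs, 0.0)
        coefs_all.append(np.mean(coefs))
        sig += p < alpha
    return {"fraction_significant": sig / n_replicates,
            "mean_ppi_coef": float(np.mean(coefs_all)),
            "n_replicates": n_replicates, "n_subjects": n_subjects}
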