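"""ROI timecourse inference: epoching, per-timepoint OLS, LOO peaks, PPI.

The analysis contract: voxel-average and z-normalise each ROI timecourse,
upsample it 20x with cubic splines, epoch it in 10-s windows from 2 s before
to 8 s after each offer onset, fit a small OLS model independently at every
epoch timepoint, and test regressors at the group level with a leave-one-out
peak procedure — each subject's effect is read out at the peak time defined
by the remaining subjects, which removes temporal selection bias (under the
null the read-out time is independent of the left-out subject's data, so the
one-sample t-test is calibrated).  Families of ROI tests are Holm-Bonferroni
corrected.  The psychophysiological-interaction fit regresses a target
timecourse on the seed, the seed-by-environment product and nuisance terms.
No pre-whitening is applied; serial correlation is part of the calibration
contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

from .mixedlogit import FitResult
from .neural import DEFAULT_TR, ROITimecourse, VoxelDataset, env_at_times

__all__ = [
    "EpochedSignal",
    "TimecourseBetas",
    "GroupEffect",
    "preprocess_roi",
    "upsample_and_epoch",
    "pointwise_glm",
    "loo_peak_estimate",
    "group_contrasts",
    "holm_adjust",
    "ppi_fit",
    "epoch_grid",
    "ROI_GLM_REGISTRY",
]

logger = logging.getLogger(__name__)

EPOCH_START = -2.0  # seconds relative to offer onset
EPOCH_END = 8.0
PEAK_WINDOW = (0.0, 8.0)  # LOO peak search, post-onset only


def epoch_grid(tr: float = DEFAULT_TR) -> np.ndarray:
    """Epoch time grid at TR/20 spacing spanning [-2, 8) s around onset."""
    dt = tr / 20.0
    n = int(np.floor((EPOCH_END - EPOCH_START) / dt)) + 1
    return EPOCH_START + dt * np.arange(n)


@dataclass
class EpochedSignal:
    subject: str
    roi: str
    trial_rows: np.ndarray  # positional rows into the events table
    grid: np.ndarray        # seconds relative to offer onset
    data: np.ndarray        # trials x timepoints


@dataclass
class TimecourseBetas:
    subject: str
    roi: str
    regressors: list
    grid: np.ndarray
    betas: np.ndarray  # regressors x timepoints

    def series(self, regressor: str) -> np.ndarray:
        return self.betas[self.regressors.index(regressor)]


@dataclass
class GroupEffect:
    regressor: str
    roi: str
    loo_betas: np.ndarray   # one LOO peak estimate per subject
    peak_times: np.ndarray  # peak time per leave-one-out fold
    tstat: float
    p: float
    p_holm: float | None = None

    @property
    def n(self) -> int:
        return len(self.loo_betas)

    @property
    def mean_peak_time(self) -> float:
        return float(np.mean(self.peak_times))


def preprocess_roi(tc) -> ROITimecourse:
    """Voxel-average (if needed) then z-normalise to mean 0, SD 1."""
    if isinstance(tc, VoxelDataset):
        samples = tc.data.mean(axis=1)
        roi, tr = tc.roi, tc.tr
        offset = 0.0
    else:
        samples, roi, tr, offset = tc.samples, tc.roi, tc.tr, tc.start_offset
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    sd = samples.std()
    if sd == 0:
        raise ValueError(f"ROI {roi!r} timecourse is constant (zero variance)")
    return ROITimecourse(roi, tr, (samples - samples.mean()) / sd, offset)


def upsample_and_epoch(tc: ROITimecourse, events: pd.DataFrame,
                       subject: str | None = None) -> EpochedSignal:
    """Cubic-spline upsample to TR/20 and extract per-trial epochs.

    Trials whose window would leave the sampled session are dropped with a
    warning.  Epochs of adjacent trials may overlap; that is intentional.
    """
    times = tc.times
    grid = epoch_grid(tc.tr)
    spline = CubicSpline(times, tc.samples)
    onsets = events["onset_s"].to_numpy(dtype=float)
    ok = ((onsets + grid[0] >= times[0]) & (onsets + grid[-1] <= times[-1]))
    if not ok.all():
        logger.warning("dropping %d trial(s) with epoch windows outside the "
                       "session", int((~ok).sum()))
    rows = np.where(ok)[0]
    sample_times = onsets[rows, None] + grid[None, :]
    data = spline(sample_times)
    return EpochedSignal(subject or str(events["subject"].iloc[0]),
                         tc.roi, rows, grid, data)


# ---------------------------------------------------------------------------
# Per-timepoint GLMs
# ---------------------------------------------------------------------------

def _mid_mask(ev: pd.DataFrame, option_value: float) -> np.ndarray:
    return (ev["option_value"] == option_value).to_numpy()


def _dir_cong(ev: pd.DataFrame, direction: str, congruence: str) -> np.ndarray:
    return ((ev["switch_direction"] == f"{direction}-switch")
            & (ev["congruence"] == congruence)).to_numpy()


ROI_GLM_REGISTRY: dict = {
    # regressor-of-interest builders: (subset, regressor values, name)
    "4.1a": dict(name="policy_switch",
                 subset=lambda ev, v: np.ones(len(ev), dtype=bool),
                 values=lambda ev: np.nan_to_num(
                     ev["policy_switch"].to_numpy(dtype=float))),
    "4.1b": dict(name="action_switch",
                 subset=lambda ev, v: np.ones(len(ev), dtype=bool),
                 values=lambda ev: np.nan_to_num(
                     ev["action_switch"].to_numpy(dtype=float))),
    "4.2a": dict(name="congruent_pursue",
                 subset=lambda ev, v: _mid_mask(ev, v) & (ev["env"] == "poor").to_numpy(),
                 values=lambda ev: _dir_cong(ev, "pursue", "congruent").astype(float)),
    "4.2b": dict(name="incongruent_pursue",
                 subset=lambda ev, v: _mid_mask(ev, v) & (ev["env"] == "rich").to_numpy(),
                 values=lambda ev: _dir_cong(ev, "pursue", "incongruent").astype(float)),
    "4.2c": dict(name="congruent_reject",
                 subset=lambda ev, v: _mid_mask(ev, v) & (ev["env"] == "rich").to_numpy(),
                 values=lambda ev: _dir_cong(ev, "reject", "congruent").astype(float)),
    "4.2d": dict(name="incongruent_reject",
                 subset=lambda ev, v: _mid_mask(ev, v) & (ev["env"] == "poor").to_numpy(),
                 values=lambda ev: _dir_cong(ev, "reject", "incongruent").astype(float)),
    "4.4": dict(name="env_type",
                subset=lambda ev, v: np.ones(len(ev), dtype=bool),
                values=lambda ev: ev["env_code"].to_numpy(dtype=float)),
    "4.5": dict(name="congruent_change",
                subset=lambda ev, v: _mid_mask(ev, v),
                values=lambda ev: (_dir_cong(ev, "pursue", "congruent").astype(float)
                                   - _dir_cong(ev, "reject", "congruent"))),
}


def pointwise_glm(epochs: EpochedSignal, events: pd.DataFrame, glm_id: str,
                  option_value: float = 10.0) -> TimecourseBetas:
    """OLS of the epoch matrix on [constant, regressor, z(trial)] per timepoint.

    The registry defines each model's regressor of interest and trial subset
    (e.g. congruent pursue-switches against all other mid-option trials in
    poor blocks).  A z-scored trial-number regressor is always included.
    """
    if glm_id not in ROI_GLM_REGISTRY:
        raise KeyError(f"unknown glm_id {glm_id!r}; registered: "
                       f"{sorted(ROI_GLM_REGISTRY)}")
    spec = ROI_GLM_REGISTRY[glm_id]
    ev = events.iloc[epochs.trial_rows].reset_index(drop=True)
    keep = spec["subset"](ev, option_value)
    if keep.sum() < 3:
        raise ValueError(f"GLM {glm_id}: fewer than 3 trials in subset")
    x = spec["values"](ev)[keep]
    trial = ev["trial"].to_numpy(dtype=float)[keep]
    tz = (trial - trial.mean()) / trial.std() if trial.std() > 0 else trial * 0.0
    X = np.column_stack([np.ones(keep.sum()), x, tz])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"GLM {glm_id}: rank-deficient design (constant or collinear "
            f"regressor {spec['name']!r} in this subset)")
    Y = epochs.data[keep]
    betas = np.linalg.pinv(X) @ Y  # regressors x timepoints
    return TimecourseBetas(epochs.subject, epochs.roi,
                           ["constant", spec["name"], "trial_number"],
                           epochs.grid, betas)


# ---------------------------------------------------------------------------
# Group inference
# ---------------------------------------------------------------------------

def _loo_readout(B: np.ndarray, win_idx: np.ndarray):
    """LOO peak readout: subject betas at the peak time of the other subjects."""
    n = B.shape[0]
    loo = np.empty(n)
    peaks = np.empty(n, dtype=int)
    totals = B.sum(axis=0)
    for s in range(n):
        mean_others = (totals - B[s]) / (n - 1)
        k = win_idx[np.argmax(np.abs(mean_others[win_idx]))]
        loo[s] = B[s, k]
        peaks[s] = k
    return loo, peaks


def _tstat(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(x.mean() / (sd / np.sqrt(len(x))))


def loo_peak_estimate(betas: list[TimecourseBetas], regressor: str,
                      window: tuple = PEAK_WINDOW,
                      n_flips: int = 999, flip_seed: int = 0) -> GroupEffect:
    """Leave-one-out peak readout with a sign-flip group test.

    For each subject, the peak time maximises the absolute mean effect of the
    remaining subjects inside the search window (ties break to the earliest
    time); the subject's own beta at that time enters the group statistic.
    The search runs post-onset only: haemodynamic effects before the event
    would be acausal.

    The group statistic is the one-sample t of the readouts, but its p-value
    is computed by sign-flip randomisation of whole subject curves, with the
    LOO readout recomputed inside every flip.  A naive t-test on the readouts
    is anticonservative under the global null: each fold's peak is selected
    partly on the *other* subjects' noise, which correlates the readouts even
    though every single readout is unbiased.  Re-running the selection under
    random sign flips (valid because subjects are independent and their null
    beta curves sign-symmetric) restores exact calibration while keeping the
    peak readout as the effect estimate.
    """
    if len(betas) < 3:
        raise ValueError("need at least 3 subjects")
    grid = betas[0].grid
    B = np.stack([b.series(regressor) for b in betas])  # subjects x time
    win_idx = np.where((grid >= window[0]) & (grid <= window[1]))[0]
    n = B.shape[0]
    loo, peaks = _loo_readout(B, win_idx)
    t_obs = _tstat(loo)
    if np.allclose(B, 0.0):
        return GroupEffect(regressor, betas[0].roi, loo, grid[peaks], 0.0, 1.0)
    rng = np.random.default_rng(flip_seed)
    flips = rng.choice([-1.0, 1.0], size=(n_flips, n))
    Bw = B[:, win_idx]
    totals_f = flips @ Bw  # flips x window-time
    loo_f = np.empty((n_flips, n))
    for s in range(n):
        mean_others = (totals_f - np.outer(flips[:, s], Bw[s])) / (n - 1)
        k = np.argmax(np.abs(mean_others), axis=1)
        loo_f[:, s] = flips[:, s] * Bw[s, k]
    sd = loo_f.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_f = np.where(sd > 0, loo_f.mean(axis=1) / (sd / np.sqrt(n)), 0.0)
    exceed = 1 + int(np.sum(np.abs(t_f) >= abs(t_obs) - 1e-12))
    p = exceed / (n_flips + 1)
    return GroupEffect(regressor, betas[0].roi, loo, grid[peaks], t_obs, float(p))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values for one declared family."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def group_contrasts(effects: dict, pairs: list[tuple]) -> pd.DataFrame:
    """Paired t-tests between named GroupEffects, Holm-adjusted as one family."""
    rows = []
    for a, b in pairs:
        ea, eb = effects[a], effects[b]
        if ea.n != eb.n:
            raise ValueError(f"mismatched subject sets for {a} vs {b}")
        diff = ea.loo_betas - eb.loo_betas
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(ea.loo_betas, eb.loo_betas)
        rows.append({"contrast": f"{a}-vs-{b}", "n": ea.n,
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def effects_table(effects: list[GroupEffect], family: bool = True) -> pd.DataFrame:
    """Tidy summary of group effects; Holm across the list as one family."""
    out = pd.DataFrame({
        "roi": [e.roi for e in effects],
        "regressor": [e.regressor for e in effects],
        "n": [e.n for e in effects],
        "t": [e.tstat for e in effects],
        "p": [e.p for e in effects],
        "mean_peak_time": [e.mean_peak_time for e in effects],
    })
    if family and len(effects) > 1:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
        for e, ph in zip(effects, out["p_holm"]):
            e.p_holm = float(ph)
    return out


# ---------------------------------------------------------------------------
# Psychophysiological interaction
# ---------------------------------------------------------------------------

def ppi_fit(target: ROITimecourse, seed: ROITimecourse,
            events: pd.DataFrame) -> FitResult:
    """OLS of target on [constant, z(seed), z(seed) x centred env, env, trial].

    The interaction regressor is the elementwise product of the z-scored seed
    and the mean-centred rich=1/poor=0 block indicator; the seed enters as
    measured (no haemodynamic deconvolution).
    """
    y = np.asarray(target.samples, dtype=float)
    s = np.asarray(seed.samples, dtype=float)
    if len(y) != len(s):
        raise ValueError("target and seed timecourses differ in length")
    times = target.times
    env = env_at_times(events, times)
    zs = (s - s.mean()) / s.std()
    ppi = zs * (env - env.mean())
    onsets = np.sort(events["onset_s"].to_numpy(dtype=float))
    trial_count = np.searchsorted(onsets, times, side="right").astype(float)
    tz = (trial_count - trial_count.mean())
    if tz.std() > 0:
        tz = tz / tz.std()
    X = np.column_stack([np.ones(len(y)), zs, ppi, env, tz])
    terms = ["intercept", "seed", "ppi", "env_type", "trial_number"]
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / max(dof, 1)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), max(dof, 1))
    return FitResult(terms=terms, coef=coef, se=se, zvalues=tvals,
                     pvalues=pvals, random_terms=[], random_sd=np.array([]),
                     n_obs=len(y), n_groups=1, converged=bool(rank == X.shape[1]),
                     loglik=np.nan, meta={"glm_id": "4.3"})
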