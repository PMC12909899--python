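"""Synthetic BOLD with planted, recoverable effects.

Generates (i) per-ROI univariate timecourses in which chosen event types
(e.g. environment-congruent pursue- or reject-switches) carry planted
haemodynamic amplitudes on top of AR(1) Gaussian noise, with optional
environment-modulated seed-to-target coupling, and (ii) per-ROI voxel
timeseries in which each offer type evokes a multivoxel pattern whose
geometry is warped by the environment: in poor blocks the mid option's
pattern is pulled a fraction ``kappa`` of the way toward the high option's
pattern.  Everything is driven by an event table from the task simulator and
a double-gamma haemodynamic response function, and is bit-reproducible under
a seed.

Amplitudes are expressed in units of the noise SD so that downstream
detection thresholds are portable across noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

__all__ = [
    "HRFSpec",
    "ROITimecourse",
    "VoxelDataset",
    "CouplingSpec",
    "GeometrySpec",
    "NeuralPlantSpec",
    "double_gamma_hrf",
    "build_design",
    "env_at_times",
    "ar1_noise",
    "synthesize_roi_bold",
    "synthesize_voxel_data",
    "session_duration",
    "DEFAULT_TR",
]

DEFAULT_TR = 1.775  # seconds
BOXCAR_DURATION = 0.1  # seconds; event regressors are brief boxcars
UPSAMPLE = 20  # design built on a TR/UPSAMPLE grid


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma haemodynamic response: peak minus scaled undershoot."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0  # peak:undershoot amplitude ratio
    length: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay, self.peak_dispersion,
               self.undershoot_dispersion, self.length) <= 0:
            raise ValueError("HRF shape parameters must be positive")
        if self.ratio <= 0:
            raise ValueError("peak:undershoot ratio must be positive")


def double_gamma_hrf(spec: HRFSpec, dt: float) -> np.ndarray:
    """HRF kernel samples on a dt grid, normalised to unit peak; kernel(0)=0."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, spec.length + dt / 2, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - under / spec.ratio
    return h / np.max(h)


@dataclass
class ROITimecourse:
    roi: str
    tr: float
    samples: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("timecourse samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_offset + self.tr * np.arange(len(self.samples))


@dataclass
class VoxelDataset:
    roi: str
    tr: float
    data: np.ndarray  # samples x voxels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("voxel data must be samples x voxels")


@dataclass(frozen=True)
class CouplingSpec:
    """Environment-modulated seed-to-target gain."""

    seed_roi: str
    target_roi: str
    gain_rich: float = 0.0
    gain_poor: float = 0.0


@dataclass(frozen=True)
class GeometrySpec:
    """Planted multivoxel option geometry for one ROI."""

    n_voxels: int = 40
    kappa: float = 0.0          # poor-block warp of mid toward high, in [0, 1]
    pattern_noise_sd: float = 1.0
    amplitude: float = 1.0      # event-locked pattern amplitude, in noise-SD units
    orthonormal: bool = True    # base patterns from a random orthonormal frame

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.n_voxels < 2:
            raise ValueError("need at least 2 voxels")


@dataclass(frozen=True)
class NeuralPlantSpec:
    """Planted univariate amplitudes, noise model and coupling.

    ``amplitudes`` maps roi -> {event column filter -> amplitude in noise-SD
    units}; the event filter names a binary/contrast column of the coded trial
    table (e.g. ``congruent_pursue``).  Noise is AR(1) Gaussian.
    """

    amplitudes: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    ar1: float = 0.3
    couplings: tuple = ()
    hrf: HRFSpec = HRFSpec()

    def __post_init__(self) -> None:
        if not (-1.0 < self.ar1 < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        for roi, amps in self.amplitudes.items():
            for ev, a in amps.items():
                if not np.isfinite(a):
                    raise ValueError(f"amplitude {roi}/{ev} must be finite")


def session_duration(events: pd.DataFrame, pad: float = 24.0) -> float:
    """Session length covering the last event plus an HRF tail."""
    last = np.nanmax(events[["onset_s", "go_cue_onset_s", "feedback_onset_s"]]
                     .to_numpy(dtype=float))
    return float(last + pad)


def build_design(events: pd.DataFrame, regressors: list, tr: float,
                 hrf: HRFSpec | None = None, n_scans: int | None = None,
                 onset_column: str = "onset_s") -> tuple[np.ndarray, list]:
    """HRF-convolved design matrix sampled on the TR grid.

    ``regressors`` is a list of ``(name, mask, modulation)`` triples: ``mask``
    selects the events whose onsets receive a 0.1-s boxcar, ``modulation`` is
    an optional per-event parametric height (None for unmodulated).  Returns
    ``(design, warnings)`` where empty regressors yield a zero column and a
    warning string.
    """
    hrf = hrf or HRFSpec()
    if n_scans is None:
        n_scans = int(np.ceil(session_duration(events) / tr))
    dt = tr / UPSAMPLE
    n_fine = n_scans * UPSAMPLE
    kernel = double_gamma_hrf(hrf, dt)
    box_len = max(1, int(round(BOXCAR_DURATION / dt)))
    onsets_all = events[onset_column].to_numpy(dtype=float)

    # events are sparse, so accumulate the (boxcar * HRF) response directly
    # at each onset instead of convolving dense stick functions
    kernel_box = np.convolve(kernel, np.ones(box_len))
    klen = len(kernel_box)
    cols = np.zeros((n_fine, len(regressors)))
    warnings = []
    for j, (name, mask, modulation) in enumerate(regressors):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            warnings.append(f"regressor {name!r} matches no events; zero column")
            continue
        onsets = onsets_all[mask]
        if np.any(onsets < 0) or np.any(onsets > n_fine * dt):
            raise ValueError(f"regressor {name!r} has onsets outside the session")
        heights = (np.ones(mask.sum()) if modulation is None
                   else np.asarray(modulation, dtype=float)[mask]
                   if np.size(modulation) == len(mask)
                   else np.asarray(modulation, dtype=float))
        idx = np.minimum((onsets / dt).astype(int), n_fine - 1)
        for i, h in zip(idx, heights):
            stop = min(i + klen, n_fine)
            cols[i:stop, j] += h * kernel_box[:stop - i]
    return cols[::UPSAMPLE], warnings


def env_at_times(events: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Rich=1/poor=0 block indicator resampled to arbitrary times.

    Block boundaries are taken midway between the last onset of one block and
    the first onset of the next; times before the first block take its label.
    """
    ev = events.sort_values("onset_s")
    blocks = ev.groupby("block").agg(env=("env", "first"),
                                     first=("onset_s", "min"),
                                     last=("onset_s", "max")).sort_index()
    codes = (blocks["env"] == "rich").astype(float).to_numpy()
    bounds = 0.5 * (blocks["last"].to_numpy()[:-1] + blocks["first"].to_numpy()[1:])
    return codes[np.searchsorted(bounds, np.asarray(times, dtype=float))]


def ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal SD ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    e = innov_sd * rng.standard_normal(n)
    x0 = sd * rng.standard_normal()  # stationary start carried via filter state
    x, _ = sps.lfilter([1.0], [1.0, -phi], e, zi=np.array([phi * x0]))
    return x


def _event_mask(events: pd.DataFrame, event_name: str) -> np.ndarray:
    """Binary event filter over trials, by coded-column convention.

    Supported names: ``all``, ``congruent_pursue``, ``incongruent_pursue``,
    ``congruent_reject``, ``incongruent_reject``, ``policy_switch``,
    ``action_switch``, ``pursue``, ``reject``, or any 0/1 column of the table.
    """
    dirn = events.get("switch_direction")
    cong = events.get("congruence")
    if event_name == "all":
        return np.ones(len(events), dtype=bool)
    if event_name in ("congruent_pursue", "incongruent_pursue",
                      "congruent_reject", "incongruent_reject"):
        if dirn is None or cong is None:
            raise ValueError("events table must be coded (switch_direction/congruence)")
        want_cong, want_dir = event_name.split("_")
        return ((dirn == f"{want_dir}-switch")
                & (cong == f"{want_cong}")).to_numpy()
    if event_name in ("policy_switch", "action_switch"):
        return (events[event_name] == 1).to_numpy()
    if event_name == "pursue":
        return (events["decision"] == 1).to_numpy()
    if event_name == "reject":
        return (events["decision"] == 0).to_numpy()
    if event_name in events.columns:
        return (events[event_name] == 1).to_numpy()
    raise KeyError(f"unknown event filter {event_name!r}")


def synthesize_roi_bold(events: pd.DataFrame, plant: NeuralPlantSpec,
                        rng: np.random.Generator,
                        tr: float = DEFAULT_TR) -> dict[str, ROITimecourse]:
    """Per-ROI univariate BOLD: planted event responses + AR(1) noise + coupling.

    Signal amplitudes are in noise-SD units; coupling targets additionally
    receive ``gain(env) * z(seed)`` sample-wise.  Returns roi -> timecourse.
    """
    n_scans = int(np.ceil(session_duration(events) / tr))
    out: dict[str, np.ndarray] = {}
    rois = list(plant.amplitudes)
    for c in plant.couplings:
        for r in (c.seed_roi, c.target_roi):
            if r not in rois:
                rois.append(r)
    for roi in rois:
        amps = plant.amplitudes.get(roi, {})
        y = ar1_noise(n_scans, plant.noise_sd, plant.ar1, rng)
        if amps:
            regs = [(ev, _event_mask(events, ev), None) for ev in amps]
            X, _ = build_design(events, regs, tr, plant.hrf, n_scans)
            y = y + X @ (np.array(list(amps.values())) * plant.noise_sd)
        out[roi] = y
    times = tr * np.arange(n_scans)
    env = env_at_times(events, times)
    for c in plant.couplings:
        seed = out[c.seed_roi]
        zseed = (seed - seed.mean()) / seed.std()
        gain = np.where(env == 1.0, c.gain_rich, c.gain_poor)
        out[c.target_roi] = out[c.target_roi] + gain * zseed * plant.noise_sd
    return {roi: ROITimecourse(roi, tr, y) for roi, y in out.items()}


def _base_patterns(geom: GeometrySpec, rng: np.random.Generator) -> dict:
    if geom.orthonormal:
        m = rng.standard_normal((geom.n_voxels, 3))
        q, _ = np.linalg.qr(m)
        b = {lab: q[:, i] for i, lab in enumerate(("low", "mid", "high"))}
    else:
        b = {lab: rng.standard_normal(geom.n_voxels) for lab in ("low", "mid", "high")}
        for lab in b:
            b[lab] = b[lab] / np.linalg.norm(b[lab])
    if np.linalg.matrix_rank(np.column_stack(list(b.values()))) < 3:
        raise ValueError("base patterns must be linearly independent")
    return b


def synthesize_voxel_data(events: pd.DataFrame, geom: GeometrySpec,
                          rng: np.random.Generator, roi: str = "roi",
                          hrf: HRFSpec | None = None,
                          tr: float = DEFAULT_TR) -> VoxelDataset:
    """Voxel timeseries with an environment-warped mid-option pattern.

    Low and high offers evoke their base patterns in both environments; the
    mid offer evokes its base pattern in rich blocks and, in poor blocks, the
    unit-normalised mixture (1-kappa)*b_mid + kappa*b_high.  Event responses
    are HRF-convolved 0.1-s boxcars scaled by ``amplitude`` (noise-SD units),
    plus white voxel noise.
    """
    base = _base_patterns(geom, rng)
    mid_poor = (1.0 - geom.kappa) * base["mid"] + geom.kappa * base["high"]
    nrm = np.linalg.norm(mid_poor)
    if nrm == 0:
        raise ValueError("degenerate warp: mid-poor pattern has zero norm")
    mid_poor = mid_poor / nrm

    n_scans = int(np.ceil(session_duration(events) / tr))
    env_code = (events["env"] == "rich").to_numpy()
    lab = events["option_label"].to_numpy()
    conds = {
        "low": lab == "low",
        "high": lab == "high",
        "mid_rich": (lab == "mid") & env_code,
        "mid_poor": (lab == "mid") & ~env_code,
    }
    patterns = {"low": base["low"], "high": base["high"],
                "mid_rich": base["mid"], "mid_poor": mid_poor}
    regs = [(name, mask, None) for name, mask in conds.items()]
    X, _ = build_design(events, regs, tr, hrf, n_scans)
    amp = geom.amplitude * geom.pattern_noise_sd if geom.pattern_noise_sd > 0 \
        else geom.amplitude
    P = np.column_stack([patterns[name] for name, _, _ in regs])  # voxels x 4
    data = X @ (amp * P.T)
    if geom.pattern_noise_sd > 0:
        data = data + geom.pattern_noise_sd * rng.standard_normal(data.shape)
    return VoxelDataset(roi, tr, data)
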