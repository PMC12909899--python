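"""Environment-conditioned representational similarity analysis.

Estimates one multivoxel activity pattern per (offer option x block) cell by
OLS with onset regressors (up to 30 cells: 3 options x 10 blocks), then
compares option pairs across non-contiguous blocks of the same environment.
Distances are cosine dissimilarity (1 - cosine) or 1 - Pearson correlation,
both insensitive to univariate scaling (Pearson also to additive shifts).

"Block-space" is the number of intervening blocks between two blocks (blocks
4 and 6 are one block apart).  Distances at each block-space level are
averaged, only levels attainable in both environments are retained (so rich
and poor estimates are matched), and retained levels are averaged with equal
weight.  The four headline distances are d1 = (low, mid | poor),
d2 = (mid, high | poor), d3 = (low, mid | rich), d4 = (mid, high | rich),
with contrast scores H1 = d1 - d3 and H2 = d4 - d2: a positive H2 means the
mid option's pattern sits closer to the high option's in poor environments
than in rich ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .neural import HRFSpec, VoxelDataset, build_design
from .roi import holm_adjust

__all__ = [
    "PatternSet",
    "DistanceSummary",
    "estimate_patterns",
    "pattern_distance",
    "matched_block_distances",
    "rsa_scores",
    "rsa_brain_behaviour",
]

OPTION_ORDER = ("low", "mid", "high")


@dataclass
class PatternSet:
    roi: str
    subject: str
    patterns: dict  # (option label, block index) -> voxel vector
    block_env: dict  # block index -> "rich" | "poor"

    def blocks(self, env: str) -> list:
        return sorted(b for b, e in self.block_env.items() if e == env)

    def get(self, option: str, block: int):
        return self.patterns.get((option, block))


@dataclass
class DistanceSummary:
    subject: str
    roi: str
    metric: str
    d1: float
    d2: float
    d3: float
    d4: float
    levels_used: tuple

    @property
    def h1(self) -> float:
        return self.d1 - self.d3

    @property
    def h2(self) -> float:
        return self.d4 - self.d2


def estimate_patterns(voxels: VoxelDataset, events: pd.DataFrame,
                      hrf: HRFSpec | None = None,
                      subject: str | None = None) -> PatternSet:
    """Per-(option x block) pattern estimates from one OLS fit per voxel.

    The design holds one unmodulated 0.1-s-boxcar onset regressor per
    non-empty (option, block) cell, plus a constant and a z-scored
    trial-number nuisance regressor; empty cells are simply absent.
    """
    lab = events["option_label"].to_numpy()
    blk = events["block"].to_numpy()
    cells = []
    for b in sorted(events["block"].unique()):
        for opt in OPTION_ORDER:
            mask = (lab == opt) & (blk == b)
            if mask.any():
                cells.append(((opt, int(b)), mask))
    regs = [(f"{opt}_b{b}", mask, None) for (opt, b), mask in cells]
    n_scans = voxels.data.shape[0]
    X, _ = build_design(events, regs, voxels.tr, hrf, n_scans)
    # nuisance: constant + linear trend over scans (proxy for trial number)
    t_scan = np.arange(n_scans, dtype=float)
    tz = (t_scan - t_scan.mean()) / t_scan.std()
    X_full = np.column_stack([X, np.ones(n_scans), tz])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise ValueError(
            "rank-deficient pattern design: some (option, block) onset "
            "regressors are collinear or empty")
    betas = np.linalg.pinv(X_full) @ voxels.data  # (cells + nuisance) x voxels
    patterns = {key: betas[i] for i, (key, _) in enumerate(cells)}
    block_env = {int(b): str(events.loc[events["block"] == b, "env"].iloc[0])
                 for b in events["block"].unique()}
    return PatternSet(voxels.roi, subject or str(events["subject"].iloc[0]),
                      patterns, block_env)


def pattern_distance(u: np.ndarray, v: np.ndarray, metric: str = "cosine") -> float:
    """Cosine dissimilarity 1 - cos(u, v) or Pearson distance 1 - corr(u, v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("patterns must be equal-length vectors of length >= 2")
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("cosine distance undefined for a zero vector")
        return float(1.0 - (u @ v) / (nu * nv))
    if metric == "pearson":
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            raise ValueError("pearson distance undefined for a constant vector")
        return float(1.0 - np.corrcoef(u, v)[0, 1])
    raise ValueError(f"unknown metric {metric!r}")


def _levels(patterns: PatternSet, pair: tuple, env: str,
            intervening: bool) -> dict:
    """distances grouped by block-space level for one pair in one environment."""
    a, b = pair
    blocks = patterns.blocks(env)
    by_level: dict = {}
    for i in blocks:
        for j in blocks:
            if j <= i or j - i < 2:  # unordered, non-contiguous pairs only
                continue
            level = (j - i - 1) if intervening else (j - i)
            for u, v in ((patterns.get(a, i), patterns.get(b, j)),
                         (patterns.get(a, j), patterns.get(b, i))):
                if u is None or v is None:
                    continue
                by_level.setdefault(level, []).append((u, v))
    return by_level


def matched_block_distances(patterns: PatternSet, pair: tuple, env: str,
                            metric: str = "cosine",
                            intervening: bool = True):
    """Mean cross-block distance for an option pair in one environment.

    Both orientations (A in the earlier block vs B in the later, and the
    mirror) contribute; distances are averaged within each block-space level,
    levels not attainable in both environments are discarded, and the
    retained level means are averaged with equal weight.  Returns
    ``(distance, levels_used)``.
    """
    this_env = _levels(patterns, pair, env, intervening)
    other = "rich" if env == "poor" else "poor"
    other_env = _levels(patterns, pair, other, intervening)
    shared = sorted(set(this_env) & set(other_env))
    if not shared:
        raise ValueError(
            f"no block-space level attainable in both environments for pair "
            f"{pair} (this env has {sorted(this_env)}, other {sorted(other_env)})")
    level_means = [float(np.mean([pattern_distance(u, v, metric)
                                  for u, v in this_env[lvl]]))
                   for lvl in shared]
    return float(np.mean(level_means)), tuple(shared)


def rsa_scores(patterns: PatternSet, metric: str = "cosine",
               intervening: bool = True) -> DistanceSummary:
    """The four environment-conditioned distances and their contrasts."""
    d1, lv1 = matched_block_distances(patterns, ("low", "mid"), "poor",
                                      metric, intervening)
    d2, lv2 = matched_block_distances(patterns, ("mid", "high"), "poor",
                                      metric, intervening)
    d3, _ = matched_block_distances(patterns, ("low", "mid"), "rich",
                                    metric, intervening)
    d4, _ = matched_block_distances(patterns, ("mid", "high"), "rich",
                                    metric, intervening)
    return DistanceSummary(patterns.subject, patterns.roi, metric,
                           d1, d2, d3, d4, tuple(sorted(set(lv1) | set(lv2))))


def summaries_frame(summaries: list[DistanceSummary]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject": [s.subject for s in summaries],
        "roi": [s.roi for s in summaries],
        "metric": [s.metric for s in summaries],
        "d1": [s.d1 for s in summaries], "d2": [s.d2 for s in summaries],
        "d3": [s.d3 for s in summaries], "d4": [s.d4 for s in summaries],
        "H1": [s.h1 for s in summaries], "H2": [s.h2 for s in summaries],
    })


def rsa_brain_behaviour(summaries: pd.DataFrame, deltas: pd.Series) -> pd.DataFrame:
    """Brain-behaviour coupling of the RSA contrasts, per ROI.

    Pearson correlation of H2 (and H1) with the per-subject behavioural
    change score, plus a two-sample t-test of H2 between environment-
    sensitive (delta >= 0) and insensitive (delta < 0) subjects.  Correlation
    and group-contrast p-values are Holm-corrected separately across the ROI
    family.  An empty group leaves the contrast undefined but keeps the
    correlations.
    """
    rows = []
    for roi, g in summaries.groupby("roi", sort=False):
        merged = g.set_index("subject").join(deltas.rename("delta"), how="inner")
        if len(merged) < 5:
            raise ValueError(f"need >= 5 subjects with H2 and delta for {roi!r}")
        if merged["H2"].std() == 0 or merged["delta"].std() == 0:
            raise ValueError(f"zero variance in H2 or delta for {roi!r}; "
                             "correlation undefined")
        r2, p2 = stats.pearsonr(merged["H2"], merged["delta"])
        if merged["H1"].std() > 0:
            r1, p1 = stats.pearsonr(merged["H1"], merged["delta"])
        else:
            r1, p1 = np.nan, np.nan
        sens = merged.loc[merged["delta"] >= 0, "H2"]
        insens = merged.loc[merged["delta"] < 0, "H2"]
        if len(sens) >= 2 and len(insens) >= 2:
            t_grp, p_grp = stats.ttest_ind(sens, insens)
        else:
            t_grp, p_grp = np.nan, np.nan
        rows.append({"roi": roi, "n": len(merged),
                     "r_H2": float(r2), "p_H2": float(p2),
                     "r_H1": float(r1), "p_H1": float(p1),
                     "t_group": float(t_grp), "p_group": float(p_grp),
                     "n_sensitive": int(len(sens)),
                     "n_insensitive": int(len(insens))})
    out = pd.DataFrame(rows)
    out["p_H2_holm"] = holm_adjust(out["p_H2"].to_numpy())
    grp = out["p_group"].to_numpy()
    ok = np.isfinite(grp)
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok] = holm_adjust(grp[ok])
    out["p_group_holm"] = adj
    return out
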