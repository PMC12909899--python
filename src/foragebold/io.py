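"""Event-table and configuration I/O.

Event tables are tab-separated with a fixed header and the BIDS-events
convention of ``n/a`` for missing values (the feedback onset of rejected
trials).  Floats are written with six decimals so that a write-read-write
round trip is byte-identical.  Task configuration is read from a YAML
document mirroring the TaskConfig fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import (EnvironmentSpec, RewardOption, TaskConfig, TimingSpec,
                   TruncExpSpec)

__all__ = [
    "read_events", "write_events", "read_task_config", "EVENT_COLUMNS",
    "write_timecourses", "read_timecourses", "write_voxels", "read_voxels",
    "write_patterns",
]

EVENT_COLUMNS = [
    "subject", "round", "block", "env", "trial", "trial_in_block",
    "onset_s", "go_cue_onset_s", "feedback_onset_s",
    "option_value", "decision", "reward",
]
_FLOAT_COLS = ["onset_s", "go_cue_onset_s", "feedback_onset_s",
               "option_value", "reward"]
_INT_COLS = ["round", "block", "trial", "trial_in_block", "decision"]


def write_events(events: pd.DataFrame, path) -> None:
    """Write the canonical event TSV; missing feedback onsets become ``n/a``."""
    df = events.copy()
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    out = df[EVENT_COLUMNS].copy()
    for c in _FLOAT_COLS:
        out[c] = out[c].map(lambda x: "n/a" if pd.isna(x) else f"{float(x):.6f}")
    for c in _INT_COLS:
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_events(path) -> pd.DataFrame:
    """Read an event TSV; inverse of :func:`write_events` on valid tables."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed event table {path}: {err}") from err
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} is missing columns: {missing}")
    for c in _FLOAT_COLS:
        bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()
                       & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"event table {path}: non-numeric value in column {c!r} at "
                f"line {int(bad[0]) + 2}")  # +2: header + 1-based
        df[c] = pd.to_numeric(df[c])
    for c in _INT_COLS:
        df[c] = df[c].astype(int)
    df["subject"] = df["subject"].astype(str)
    values = {5.0: "low", 10.0: "mid", 50.0: "high"}
    df["option_label"] = df["option_value"].map(
        lambda v: values.get(float(v), "mid"))
    return df


def _trunc(node) -> TruncExpSpec:
    return TruncExpSpec(float(node["mu"]), float(node["lo"]), float(node["hi"]))


def read_task_config(path) -> TaskConfig:
    """Build a TaskConfig from a YAML document mirroring its fields."""
    doc = yaml.safe_load(Path(path).read_text())
    opts = tuple(RewardOption(o["label"], float(o["value"]))
                 for o in doc["options"])
    envs = tuple(EnvironmentSpec(e["env_type"],
                                 {k: float(v) for k, v in e["offer_probs"].items()})
                 for e in doc["environments"])
    t = doc.get("timing", {})
    timing = TimingSpec(
        iti=_trunc(t["iti"]) if "iti" in t else TimingSpec().iti,
        opportunity_delay=(_trunc(t["opportunity_delay"])
                           if "opportunity_delay" in t
                           else TimingSpec().opportunity_delay),
        action_outcome_delay=(_trunc(t["action_outcome_delay"])
                              if "action_outcome_delay" in t
                              else TimingSpec().action_outcome_delay),
        feedback_delay=(_trunc(t["feedback_delay"]) if "feedback_delay" in t
                        else TimingSpec().feedback_delay),
        response_window=float(t.get("response_window", 1.0)),
        block_duration=float(t.get("block_duration", 270.0)),
        rounds=int(t.get("rounds", 5)),
        blocks_per_round=int(t.get("blocks_per_round", 2)),
        inter_round_break=float(t.get("inter_round_break", 60.0)),
    )
    return TaskConfig(options=opts, environments=envs, timing=timing,
                      rng_seed=int(doc.get("rng_seed", 0)))


def write_timecourses(timecourses: dict, path) -> None:
    """ROI timecourses as TSV: a time column plus one column per ROI."""
    tcs = list(timecourses.values())
    if len({len(tc.samples) for tc in tcs}) != 1:
        raise ValueError("all ROI timecourses must share a length")
    out = pd.DataFrame({"time_s": tcs[0].times})
    for roi, tc in timecourses.items():
        out[roi] = tc.samples
    out.to_csv(path, sep="\t", index=False, float_format="%.6f",
               lineterminator="\n")


def read_timecourses(path) -> dict:
    from .neural import ROITimecourse
    df = pd.read_csv(path, sep="\t")
    times = df["time_s"].to_numpy(dtype=float)
    tr = float(np.median(np.diff(times)))
    return {roi: ROITimecourse(roi, tr, df[roi].to_numpy(dtype=float),
                               start_offset=float(times[0]))
            for roi in df.columns if roi != "time_s"}


def write_voxels(voxels, path, sidecar_path=None, seed=None, kappa=None) -> None:
    """Voxel dataset as a delimited samples x voxels matrix + JSON sidecar."""
    import json
    np.savetxt(path, voxels.data, delimiter="\t", fmt="%.6f")
    meta = {"roi": voxels.roi, "tr": voxels.tr,
            "n_samples": int(voxels.data.shape[0]),
            "n_voxels": int(voxels.data.shape[1])}
    if seed is not None:
        meta["seed"] = int(seed)
    if kappa is not None:
        meta["kappa"] = float(kappa)
    sidecar_path = sidecar_path or str(path) + ".json"
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_voxels(path, sidecar_path=None):
    import json
    from .neural import VoxelDataset
    sidecar_path = sidecar_path or str(path) + ".json"
    meta = json.loads(Path(sidecar_path).read_text())
    data = np.loadtxt(path, delimiter="\t")
    return VoxelDataset(meta["roi"], float(meta["tr"]), np.atleast_2d(data))


def write_patterns(patterns, path) -> None:
    """PatternSet as a voxels x cells matrix with 'option_block' headers."""
    keys = sorted(patterns.patterns, key=lambda k: (k[1], k[0]))
    out = pd.DataFrame({f"{opt}_{blk}": patterns.patterns[(opt, blk)]
                        for opt, blk in keys})
    out.to_csv(path, sep="\t", index=False, float_format="%.6f",
               lineterminator="\n")
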