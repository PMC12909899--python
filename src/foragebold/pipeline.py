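"""End-to-end pipeline: simulate -> analyse -> report.

One configuration object drives every stage; a master seed fixes each stage's
random stream (stage seeds are derived by stable hashing of the stage name),
so a rerun with the same configuration reproduces every artefact, and the
report carries the configuration hash and seed as provenance.  Artefacts are
plain TSV/CSV/JSON files under the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams, CohortSpec, make_cohort, simulate_cohort_behaviour
from .behavior import code_trials, delta_pursue_rate, run_behaviour_glms
from .io import write_events
from .mixedlogit import SeparationError
from .neural import (DEFAULT_TR, CouplingSpec, GeometrySpec, NeuralPlantSpec,
                     synthesize_roi_bold, synthesize_voxel_data)
from .roi import (effects_table, loo_peak_estimate, pointwise_glm, ppi_fit,
                  preprocess_roi, upsample_and_epoch)
from .rsa import estimate_patterns, rsa_brain_behaviour, rsa_scores, summaries_frame
from .task import default_config, earnings_surface, optimal_policy

__all__ = ["PipelineConfig", "run_pipeline", "read_pipeline_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_subjects: int = 27
    master_seed: int = 0
    verbatim_probs: bool = False
    cohort_mean: AgentParams = AgentParams(beta0=-0.5, beta_value=0.15,
                                           beta_env=-1.0, beta_prev_policy=0.8)
    cohort_sd: dict = field(default_factory=lambda: {
        "sd_beta0": 0.3, "sd_beta_env": 0.8, "sd_beta_prev_policy": 0.3})
    behaviour_glms: tuple = ("1.1b", "2.1", "2.2", "2.5a", "2.5b")
    roi_glms: tuple = ("4.1a", "4.1b", "4.2a", "4.2c")
    plant: NeuralPlantSpec = NeuralPlantSpec(
        amplitudes={"DRN": {"congruent_pursue": 1.0, "congruent_reject": -1.0},
                    "dACC": {"pursue": 0.5}},
        couplings=(CouplingSpec("dACC", "DRN", gain_rich=0.0, gain_poor=0.5),))
    geometry: GeometrySpec = GeometrySpec(n_voxels=40, amplitude=2.0)
    kappa_per_adaptivity: float = 0.5
    tr: float = DEFAULT_TR
    out_dir: str = "pipeline_out"


def _stage_seed(master_seed: int, stage: str) -> int:
    return int((master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31))


def _config_hash(config: PipelineConfig) -> str:
    doc = dataclasses.asdict(config)
    doc.pop("out_dir", None)  # where artefacts land does not change them
    blob = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_pipeline_config(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("n_subjects", "master_seed", "verbatim_probs", "out_dir",
                "kappa_per_adaptivity", "tr"):
        if key in doc:
            kwargs[key] = doc[key]
    if "cohort_mean" in doc:
        kwargs["cohort_mean"] = AgentParams(**doc["cohort_mean"])
    if "cohort_sd" in doc:
        kwargs["cohort_sd"] = dict(doc["cohort_sd"])
    if "behaviour_glms" in doc:
        kwargs["behaviour_glms"] = tuple(str(g) for g in doc["behaviour_glms"])
    if "roi_glms" in doc:
        kwargs["roi_glms"] = tuple(str(g) for g in doc["roi_glms"])
    return PipelineConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artefacts; returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task = default_config(rng_seed=_stage_seed(config.master_seed, "task"),
                          verbatim_probs=config.verbatim_probs)
    report: dict = {"config_hash": _config_hash(config),
                    "master_seed": config.master_seed, "warnings": []}

    # --- optimality analysis -------------------------------------------------
    opt = {}
    for env_type in ("rich", "poor"):
        pol, rate = optimal_policy(task.environment(env_type), task)
        opt[env_type] = {"pursue_set": sorted(pol.pursue_set),
                         "points_per_slot": rate}
    _, argmax = earnings_surface(task, np.linspace(0.0, 1.0, 21))
    opt["surface_argmax"] = {"p_mid_rich": argmax[0], "p_mid_poor": argmax[1]}
    report["optimality"] = opt

    # --- behaviour -----------------------------------------------------------
    rng = np.random.default_rng(_stage_seed(config.master_seed, "behaviour"))
    spec = CohortSpec(n_subjects=config.n_subjects,
                      rng_seed=_stage_seed(config.master_seed, "cohort"),
                      **config.cohort_sd)
    cohort = make_cohort(spec, config.cohort_mean)
    trials = simulate_cohort_behaviour(task, cohort, rng)
    coded = code_trials(trials)
    write_events(coded, out / "events.tsv")
    with open(out / "cohort_params.yaml", "w") as fh:
        yaml.safe_dump([dataclasses.asdict(p) for p in cohort], fh)

    fit_rows = []
    for glm_id in config.behaviour_glms:
        try:
            fit = run_behaviour_glms(coded, glm_id)
        except SeparationError as err:
            report["warnings"].append(f"behaviour GLM {glm_id}: {err}")
            continue
        frame = fit.to_frame()
        frame.insert(0, "glm_id", glm_id)
        fit_rows.append(frame)
    fits = pd.concat(fit_rows, ignore_index=True)
    fits.to_csv(out / "behaviour_fits.csv", index=False)
    report["behaviour"] = {
        "n_trials": int(len(coded)),
        "mean_delta_pursue_rate": float(delta_pursue_rate(coded).mean()),
        "glms": {g: True for g in config.behaviour_glms},
    }

    # --- neural synthesis + ROI timecourse inference -------------------------
    rng_n = np.random.default_rng(_stage_seed(config.master_seed, "neural"))
    betas_by_glm: dict = {g: [] for g in config.roi_glms}
    ppi_coefs = []
    h2 = {}
    for (subj, ev), params in zip(coded.groupby("subject", sort=False), cohort):
        ev = ev.reset_index(drop=True)
        tcs = synthesize_roi_bold(ev, config.plant, rng_n, tr=config.tr)
        drn = preprocess_roi(tcs["DRN"])
        epochs = upsample_and_epoch(drn, ev, subject=subj)
        for glm_id in config.roi_glms:
            try:
                betas_by_glm[glm_id].append(pointwise_glm(epochs, ev, glm_id))
            except ValueError as err:
                report["warnings"].append(f"{subj} GLM {glm_id}: {err}")
        fit = ppi_fit(drn, preprocess_roi(tcs["dACC"]), ev)
        ppi_coefs.append(fit["ppi"]["coef"])

        kap = float(np.clip(config.kappa_per_adaptivity
                            * max(0.0, -params.beta_env), 0.0, 1.0))
        geom = dataclasses.replace(config.geometry, kappa=kap)
        vox = synthesize_voxel_data(ev, geom, rng_n, roi="dACC", tr=config.tr)
        pats = estimate_patterns(vox, ev, subject=subj)
        h2[subj] = rsa_scores(pats, "cosine")

    effects = [loo_peak_estimate(b, b[0].regressors[1])
               for b in betas_by_glm.values() if len(b) >= 3]
    eff_table = effects_table(effects)
    eff_table.insert(0, "glm_id", [g for g, b in betas_by_glm.items()
                                   if len(b) >= 3])
    eff_table.to_csv(out / "roi_effects.csv", index=False)
    report["roi"] = {r["glm_id"]: {"t": r["t"], "p": r["p"]}
                     for _, r in eff_table.iterrows()}

    from scipy import stats as sstats
    t_ppi, p_ppi = sstats.ttest_1samp(ppi_coefs, 0.0)
    report["ppi"] = {"mean_coef": float(np.mean(ppi_coefs)),
                     "t": float(t_ppi), "p": float(p_ppi)}

    summaries = summaries_frame(list(h2.values()))
    summaries.to_csv(out / "rsa_distances.csv", index=False)
    if config.n_subjects >= 5:
        bb = rsa_brain_behaviour(summaries, delta_pursue_rate(coded))
        bb.to_csv(out / "rsa_brain_behaviour.csv", index=False)
        report["rsa"] = bb.iloc[0][["roi", "n", "r_H2", "p_H2"]].to_dict()
    else:
        report["warnings"].append(
            "rsa brain-behaviour stage skipped: fewer than 5 subjects")
        report["rsa"] = {"mean_H2": float(summaries["H2"].mean())}

    report["n_warnings"] = len(report["warnings"])
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
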