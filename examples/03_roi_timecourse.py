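"""Recover a planted policy-switch response from synthetic ROI BOLD.

One ROI carries opposite haemodynamic responses at environment-congruent
pursue-switches (+1 noise-SD) and congruent reject-switches (-1 noise-SD).
Per subject, the z-scored timecourse is spline-upsampled, epoched around
offer onsets, and fit with per-timepoint OLS; group inference reads each
subject's effect at the peak time defined by the other subjects (leave-one-
out) and tests it by sign-flip randomisation.
"""

import numpy as np

from foragebold import (AgentParams, CohortSpec, NeuralPlantSpec, code_trials,
                        default_config, loo_peak_estimate, make_cohort,
                        pointwise_glm, preprocess_roi, simulate_cohort_behaviour,
                        synthesize_roi_bold, upsample_and_epoch)

cfg = default_config()
cohort = make_cohort(CohortSpec(n_subjects=10, sd_beta_env=0.5, rng_seed=2),
                     AgentParams(beta0=-0.3, beta_value=0.12, beta_env=-1.0,
                                 beta_prev_policy=0.8))
coded = code_trials(simulate_cohort_behaviour(cfg, cohort,
                                              np.random.default_rng(2)))

plant = NeuralPlantSpec(amplitudes={"DRN": {"congruent_pursue": 1.0,
                                            "congruent_reject": -1.0}},
                        noise_sd=1.0, ar1=0.3)
rng = np.random.default_rng(3)
betas_pursue, betas_reject = [], []
for subj, ev in coded.groupby("subject", sort=False):
    ev = ev.reset_index(drop=True)
    tc = preprocess_roi(synthesize_roi_bold(ev, plant, rng)["DRN"])
    epochs = upsample_and_epoch(tc, ev, subject=subj)
    betas_pursue.append(pointwise_glm(epochs, ev, "4.2a"))
    try:
        betas_reject.append(pointwise_glm(epochs, ev, "4.2c"))
    except ValueError:
        pass  # subject without congruent reject-switches

for name, blist in (("congruent pursue-switch", betas_pursue),
                    ("congruent reject-switch", betas_reject)):
    eff = loo_peak_estimate(blist, blist[0].regressors[1])
    print(f"{name}: n={eff.n}, mean peak beta = {eff.loo_betas.mean():+.2f} "
          f"at ~{eff.mean_peak_time:.1f} s, t = {eff.tstat:+.2f}, "
          f"p = {eff.p:.3f}")
print("Opposite signs recover the planted dissociation: the region "
      "activates for environment-appropriate switches to pursuit and "
      "deactivates for switches to rejection.")
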