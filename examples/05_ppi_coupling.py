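"""Detect environment-modulated coupling between two synthetic regions.

The target region receives gain(environment) x seed signal: gain 0.5 in poor
blocks, 0 in rich blocks.  The psychophysiological-interaction regression
(target ~ seed + seed x centred-environment + environment + trial) should
load the difference on the interaction term with a negative sign, because
the environment is coded rich = 1.
"""

import numpy as np

from foragebold import (AgentParams, CouplingSpec, NeuralPlantSpec,
                        code_trials, default_config, ppi_fit, preprocess_roi,
                        simulate_cohort_behaviour, synthesize_roi_bold)

cfg = default_config()
ev = code_trials(simulate_cohort_behaviour(cfg, [AgentParams(beta0=-0.3)],
                                           np.random.default_rng(6)))

plant = NeuralPlantSpec(
    amplitudes={"dACC": {}, "DRN": {}}, noise_sd=1.0, ar1=0.3,
    couplings=(CouplingSpec("dACC", "DRN", gain_rich=0.0, gain_poor=0.5),))
tcs = synthesize_roi_bold(ev, plant, np.random.default_rng(7))
fit = ppi_fit(preprocess_roi(tcs["DRN"]), preprocess_roi(tcs["dACC"]), ev)

for term in ("seed", "ppi", "env_type"):
    r = fit[term]
    print(f"{term:>9}: beta = {r['coef']:+.3f} +- {r['se']:.3f}, "
          f"t = {r['z']:+.2f}, p = {r['p']:.2g}")
print("\nThe negative interaction says seed-target coactivation is stronger "
      "in poor blocks (rich coded 1); the seed main effect reflects the "
      "average coupling.")
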