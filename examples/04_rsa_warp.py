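"""Environment-conditioned representational distances on synthetic patterns.

The generator warps the mid option's multivoxel pattern toward the high
option's pattern in poor blocks by a fraction kappa.  The RSA pipeline
estimates one pattern per (option x block) cell, compares option pairs
across non-contiguous same-environment blocks, and scores
H2 = d4 - d2: how much closer mid sits to high in poor than in rich blocks.
"""

import numpy as np

from foragebold import (AgentParams, GeometrySpec, code_trials, default_config,
                        estimate_patterns, rsa_scores, simulate_cohort_behaviour,
                        synthesize_voxel_data)

cfg = default_config()
trials = simulate_cohort_behaviour(cfg, [AgentParams(beta0=-0.3,
                                                     beta_value=0.12)],
                                   np.random.default_rng(4))
ev = code_trials(trials)

print("kappa   d1      d2      d3      d4      H1      H2")
for kappa in (0.0, 0.3, 0.6):
    geom = GeometrySpec(n_voxels=40, kappa=kappa, pattern_noise_sd=1.0,
                        amplitude=2.0)
    vox = synthesize_voxel_data(ev, geom, np.random.default_rng(5))
    sc = rsa_scores(estimate_patterns(vox, ev), metric="cosine")
    print(f"{kappa:.1f}   {sc.d1:6.3f}  {sc.d2:6.3f}  {sc.d3:6.3f}  "
          f"{sc.d4:6.3f}  {sc.h1:+.3f}  {sc.h2:+.3f}")
print("\nAs kappa grows, d2 (mid-high distance in poor blocks) shrinks while "
      "d4 (the same distance in rich blocks) stays put, so H2 = d4 - d2 "
      "tracks the planted warp; the noise-free kappa=0.6 value is "
      "1 - 0.6/sqrt(0.52) below 1, i.e. H2 ~ 0.832.")
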