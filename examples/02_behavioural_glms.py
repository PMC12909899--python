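"""Simulate an adaptive cohort and fit the behavioural mixed logits.

Agents pursue the mid option more readily in poor blocks (negative
environment weight, rich coded 1) and tend to repeat their last decision for
the same option (positive persistence weight).  The mixed-effects logistic
fits should recover both patterns from the simulated choices alone.
"""

import numpy as np

from foragebold import AgentParams, CohortSpec, code_trials, default_config, \
    delta_pursue_rate, make_cohort, run_behaviour_glms, simulate_cohort_behaviour

cfg = default_config(rng_seed=1)
cohort = make_cohort(
    CohortSpec(n_subjects=12, sd_beta_env=0.4, sd_beta_prev_policy=0.3,
               rng_seed=1),
    AgentParams(beta0=-0.5, beta_value=0.15, beta_env=-0.8,
                beta_prev_policy=1.0, lapse=0.05))
trials = simulate_cohort_behaviour(cfg, cohort, np.random.default_rng(1))
coded = code_trials(trials)
print(f"{len(coded)} trials from {coded['subject'].nunique()} subjects")

fit = run_behaviour_glms(coded, "1.1b")  # mid-option environment effect
e = fit["env_code"]
print(f"\nEnvironment effect on mid-option pursuit (rich=1): "
      f"beta = {e['coef']:.2f} +- {e['se']:.2f}, p = {e['p']:.2g}")
print("  negative: the mid option is pursued more in poor environments")

fit = run_behaviour_glms(coded, "2.1")  # policy persistence
p = fit["prev_policy"]
print(f"Previous-policy effect: beta = {p['coef']:.2f} +- {p['se']:.2f}, "
      f"p = {p['p']:.2g}")
fit = run_behaviour_glms(coded, "2.2")  # previous action, any option
a = fit["prev_action"]
print(f"Previous-action effect: beta = {a['coef']:.2f} +- {a['se']:.2f}, "
      f"p = {a['p']:.2g}")
print("  persistence is option-specific: strong at the same-option lag, "
      "null for the preceding trial per se")

delta = delta_pursue_rate(coded)
print(f"\nBehavioural change score Delta = pursue(poor) - pursue(rich): "
      f"mean {delta.mean():.3f} "
      f"({(delta >= 0).sum()}/{len(delta)} subjects environment-sensitive)")
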