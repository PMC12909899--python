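"""Derive the rational pursue/reject strategy from the task's reward rates.

Each encounter costs one time slot (ITI + consideration delay) and pursuing
costs one more, so an option is worth pursuing only if its value beats the
points-per-slot rate the environment offers.  This script prints the renewal
reward rate of every deterministic option policy in rich and poor
environments and the expected-earnings surface over mid-option pursuit
rates.
"""

import itertools

import numpy as np

from foragebold import Policy, default_config, earnings_surface, optimal_policy, reward_rate

cfg = default_config()

for env_type in ("rich", "poor"):
    env = cfg.environment(env_type)
    print(f"\n{env_type.upper()} environment "
          f"(offer frequencies low/mid/high = "
          f"{env.prob('low'):.3f}/{env.prob('mid'):.3f}/{env.prob('high'):.3f})")
    for r in range(4):
        for subset in itertools.combinations(("low", "mid", "high"), r):
            rate, per_s = reward_rate(Policy.from_set(subset), env, cfg)
            print(f"  pursue {set(subset) or '{}'!s:<24} "
                  f"{rate:7.3f} pts/slot  ({per_s:.3f} pts/s)")
    pol, rate = optimal_policy(env, cfg)
    print(f"  optimal: pursue {sorted(pol.pursue_set)} at {rate:.3f} pts/slot")

surface, argmax = earnings_surface(cfg, np.linspace(0, 1, 11))
print(f"\nExpected session points at the surface corners "
      f"(rows: P(pursue mid|rich), cols: P(pursue mid|poor)):")
print(np.round(surface[[0, -1]][:, [0, -1]], 1))
print(f"argmax: pursue mid with probability {argmax[0]:.0f} in rich and "
      f"{argmax[1]:.0f} in poor -> the mid option is worth pursuing only in "
      "poor environments.")
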