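"""The default synthetic study system: prey-density regimes and diet shift.

Generates the 11-prey ground truth for 2007-2024 (urchin outbreak 2014,
mussel rise from 2016, profitable-prey decline) and prints the implied
effort allocations before and after sea star wasting.
"""

import numpy as np

from otterforage import generate_ground_truth, simulate_sofa_outputs

truth = generate_ground_truth(seed=42)
eta = truth.eta_matrix()                     # (years, prey)
pre = truth.years < 2013
post = truth.years >= 2013

im = truth.prey_ids.index("mussel")
iu = truth.prey_ids.index("urchin")
print(f"urchin effort: {100*eta[pre, iu].mean():.1f}% pre ->"
      f" {100*eta[post, iu].mean():.1f}% post")
print(f"mussel effort: {100*eta[pre, im].mean():.1f}% pre ->"
      f" {100*eta[post, im].mean():.1f}% post"
      f"  ({eta[post, im].mean()/eta[pre, im].mean():.2f}-fold)")

obs = simulate_sofa_outputs(truth, n_draws=1000, seed=43)
print("observed effort rows on the simplex:",
      bool(np.allclose(obs.eta_draws.sum(axis=-1), 1.0)))
# The generator encodes the reported diet shift: a ~2.5-fold rise in mussel
# effort and an urchin increase, driven purely by prey-density regimes
# under the optimal-foraging allocation rule.
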