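# otterforage

Bayesian optimal-foraging bioenergetics of a sea otter diet shift, with
rocky-intertidal trend analyses — driven end to end by a synthetic study
system with a known ground truth.

## The scientific problem

After the 2013 sea star wasting epizootic removed the keystone intertidal
predator *Pisaster ochraceus* from the central California coast, mussels
(*Mytilus californianus*) expanded downshore toward the low-tide line,
growing larger and covering more rock — and thereby became newly accessible
to sea otters, whose kelp-forest prey were simultaneously reshuffled by a
marine heatwave (urchin outbreak, declines in abalone, crabs and other
profitable prey). This package is for quantitative ecologists who want to
model that kind of cross-ecosystem diet shift: it asks how much foraging
effort an optimal forager should allocate to each prey type as prey
densities change, what that implies for its rate of energy intake and
per-prey predation rates, and what intake *would* have been had particular
prey increases never happened.

## The model

Each prey type *i* has a latent effective density δ_{i,t} (suitable-patch
encounter rate per dive) following a log-scale random walk
Δ_{i,t} ~ N(Δ_{i,t−1}, σ_{D,i}), and a patch profitability E_i = exp(μ_i)
(kcal/min). With per-dive encounter probability λ = 1 − e^{−δ}, an optimal
forager that takes the most profitable patch it encounters allocates a dive
to prey *i* with probability

    π_{i,t} = λ_{i,t} · Π_{j: E_j > E_i} (1 − λ_{j,t}),      η_t = π_t / Σπ_t.

Observed log intake rates are Normal(μ_i, σ_{E,i}) and observed yearly
effort allocations Dirichlet(τ_t·η_t), with τ_t fixed in advance by maximum
likelihood on effort-draw matrices. The model is fitted by a blocked
adaptive MCMC sampler built for this geometry (see `docs/methods.md`), and
derived quantities follow: mean energy intake Ē_t = Σ η_{i,t}E_i, predation
rates P_{i,t} = η_{i,t}E_i/G_i (G_i = kcal per item), and counterfactual
scenarios that freeze chosen prey at their pre-disturbance density range.

A second stage handles the classical analyses: Gompertz growth fits and
extrapolation for the pre-collapse sea star series, GCV cubic smoothing
splines with bootstrap SE ribbons, Welch t tests of the pre/post mussel
distribution (distance downshore, shell size, percent cover), and census
summaries.

## Worked example

```python
import numpy as np
from otterforage import (allocation_probabilities, encounter_probability,
                         simulate_dives)

E = np.array([9.0, 4.5, 3.9])          # crab, urchin, mussel (kcal/min)
delta = np.array([0.07, 0.27, 0.14])   # patch encounters per dive
lam = encounter_probability(delta)
av = allocation_probabilities(E, lam)
sim = simulate_dives(E, lam, 1_000_000, np.random.default_rng(0))
print(np.round(av.eta, 3), np.round(sim.eta_hat, 3))
```

prints

```
[0.177 0.579 0.244] [0.177 0.579 0.244]
```

— the closed-form effort allocation and a million-dive brute-force
simulation agree: although crab patches are twice as profitable, their
rarity means an optimal forager spends most dives on urchins. The full
synthetic system behaves like the study region it emulates
(`examples/02_synthetic_study_system.py`):

```
urchin effort: 16.2% pre -> 29.4% post
mussel effort: 6.3% pre -> 16.9% post  (2.70-fold)
```

a ~2.5-fold post-wasting rise in mussel effort driven purely by the encoded
prey-density regimes. The `examples/` directory has one short script per
capability (allocation, synthetic data, model fit + scenarios, intertidal
trends), and the `otterforage` command line runs the whole pipeline:

```bash
otterforage all --small --seed 3 --out runs/demo
```

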