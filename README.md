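# neuronspan

Is the age-dependent loss of a neuron coupled to the aging process that sets
an animal's lifespan? In the *C. elegans* Parkinson's-disease model, four
cephalic (CEP) dopaminergic neurons are lost with increasing adult age, and
the question is whether the *timing* of that loss carries any information
about when the animal will die. `neuronspan` implements the statistical
machinery for answering it in cohort designs where each animal contributes a
day-resolution lifespan and a present/absent call for each neuron at one
observation day (day 7 of adulthood by default):

- **Synthetic cohorts** — Gompertz lifespans, per-neuron Weibull loss times
  with age-increasing hazard, and a tunable Spearman rank correlation
  ρ_s between each loss time and lifespan via a Gaussian copula
  (Pearson parameter r = 2 sin(πρ_s/6)). Built-in genotype scenarios:
  wild type (mean lifespan 10.5 d), *age-1* (2.6× lifespan, more severe
  ventral-neuron loss), *daf-16;age-1* and its intestinal rescue (+40%).
- **Survival statistics** — Kaplan-Meier curves and the Peto-Prentice
  Wilcoxon weighted log-rank test (weights S̃(t_j) = ∏_{i≤j}(1 − d_i/(n_i+1)),
  hypergeometric variance, tie-aware), plus restricted means and percentiles.
- **Categorical statistics** — Fisher's exact test, Pearson chi-square,
  Bonferroni adjustment, proportional-odds ordinal regression.
- **Copula power engine** — the experiment never observes the latent
  neuron-loss time, only the day-7 dichotomy. The engine simulates joint
  (lifespan-rank, neuronspan-rank) samples at each ρ_s on a grid, labels the
  k lowest neuron-span ranks "absent", maps lifespan ranks back onto the
  empirical lifespan multiset, and tests absent vs present with the
  Peto-Prentice test. Power(ρ_s) is the fraction of replicates with
  p < α; the **detection threshold** is the smallest |ρ_s| with power ≥ 0.95.
- **Pipeline + CLI** — per-neuron and grouped independence analyses with
  Bonferroni families, machine-readable JSON/CSV reports, deterministic
  seeding, and `neuronspan simulate|analyze|power|suite` subcommands.

## Worked example

```python
import numpy as np
from neuronspan import (calibrate_gompertz, sample_lifespans, discretize_to_days,
                        power_curve, detection_threshold)

params = calibrate_gompertz(10.5, 0.25)          # wild-type stand-in marginal
lifespans = discretize_to_days(sample_lifespans(params, 3397, seed=11))
curve = power_curve(lifespans, k_absent=238,     # 7% of animals missing the neuron
                    grid=np.linspace(0, 0.3, 21), replicates=500, seed=42)
for rho, p in zip(curve.grid[::5], curve.powers()[::5]):
    print(f"rho_s={rho:.3f}  power={p:.3f}")
print("detection threshold:", round(detection_threshold(curve, 0.95), 3))
```

prints

```
rho_s=0.000  power=0.050
rho_s=0.075  power=0.648
rho_s=0.150  power=0.998
rho_s=0.225  power=1.000
rho_s=0.300  power=1.000
detection threshold: 0.117
```

i.e. at zero coupling the test fires at its nominal 5% rate, power rises
steeply with the rank correlation, and a cohort of this size and absent
fraction would detect any coupling stronger than |ρ_s| ≈ 0.12 with 95%
probability — so a null result from such an experiment bounds the possible
coupling tightly.

The same analysis end-to-end on a synthetic cohort:

```
neuronspan simulate --scenario wild_type --n 3397 --seed 1 --out cohort.csv
neuronspan analyze --cohort cohort.csv --out report.json --replicates 500 --grid-points 21
```

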