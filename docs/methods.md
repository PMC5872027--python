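# Methods

## The question and the observable

Each animal in a cohort yields a lifespan measured in whole days from the L4
molt and, if it survived to the observation day (day 7 of adulthood by
default), a present/absent call for each of the four cephalic dopaminergic
neurons (CEPDL, CEPDR, CEPVL, CEPVR). The latent quantity of interest — the
*neuron-span*, the age at which a given neuron is lost — is never observed
directly; only its dichotomization at the observation day is. The package
asks whether the neuron-span and the lifespan are coupled in rank, i.e.
whether animals that lose a neuron early also tend to die early, and if an
experiment finds no association, how strong a coupling it was powered to
rule out.

## Synthetic cohort model

The generator emulates the statistical structure such experiments assume:

- **Lifespan marginal.** Gompertz mortality, hazard a·e^{gt}. The two
  parameters are calibrated to a target (mean, CV) by a 1-D root find on the
  shape ratio a/g (which alone determines the CV, increasing towards the
  exponential limit of 1) followed by a time rescale; convergence is checked
  to a relative 1e-6 and failures raise `CalibrationError`. Defaults: mean
  10.5 d for wild type (day-7 adults have lived two thirds of their expected
  lifespan), CV 0.25 — a typical breadth for isogenic nematode cohorts at
  constant temperature; 2.6× the mean for *age-1*; wild-type mean for
  *daf-16;age-1*; 1.4× that for the intestinal *daf-16* rescue.
- **Daily scoring.** Continuous lifespans are ceiling-discretized: a death
  is discovered at the first daily check at or after it occurs. This
  produces the heavy ties real day-resolution data show, which the test
  machinery must (and does) handle.
- **Neuron-loss marginal.** Per-neuron Weibull with shape k = 3 (risk
  rising with age; any k ≥ 1 is accepted) and scale set in closed form so
  that P(loss ≤ 7 d) equals the scenario's day-7 absent fraction. Weibull
  support excludes 0, so animals at the start of adulthood never show loss.
  Default day-7 absent fractions are 0.07 (each dorsal) and 0.17 (each
  ventral) for wild type — chosen so that, under conditional independence,
  the all-four-present fraction (0.93²·0.83² ≈ 0.60) matches the observed
  ~62%, with the ventral pair more severely affected than the dorsal pair —
  and (0.07, 0.07, 0.45, 0.45) for *age-1*, whose effect is ventral-specific.
  These are configuration values, not measurements.
- **Coupling.** A Gaussian copula ties each neuron's loss time to lifespan:
  one standard-normal latent drives lifespan, each neuron latent has Pearson
  correlation r = 2 sin(πρ_s/6) with it (the exact mapping from the target
  Spearman ρ_s for this family), and neurons are conditionally independent
  given the lifespan latent — no data constrain inter-neuron correlation
  beyond their common link to lifespan. Latents map through the marginal
  inverse CDFs, so the rank dependence is exactly ρ_s regardless of
  marginals.
- **Missingness.** Animals dying before the observation day are kept in the
  cohort with empty neuron states (they were never imaged); exclusion
  happens at analysis time, mirroring the real workflow.

What the generator does **not** emulate: inter-neuron dependence beyond the
shared lifespan latent, scoring error in the present/absent call,
right-censoring (real assays occasionally lose animals), temperature or
batch effects, and any particular shape of the empirical lifespan
distribution beyond its first two moments. Tests passing on synthetic
cohorts therefore validate the statistical machinery, not any biological
claim about real data.

## Survival statistics

Survival curves are Kaplan-Meier product-limit estimates (right-censoring
supported, though the assays modelled here have none). Group comparisons
use the Peto-Prentice Wilcoxon weighted log-rank test: at each distinct
pooled death time t_j with d_j deaths among n_j at risk, the weight is the
modified pooled survival estimate S̃(t_j) = ∏_{i≤j}(1 − d_i/(n_i+1)); group
scores are U_g = Σ_j w_j(d_gj − n_gj d_j/n_j) with the hypergeometric
covariance Σ_j w_j² d_j(n_j−d_j)/(n_j−1)·(n_gj/n_j)(δ_gh − n_hj/n_j); the
statistic U'V⁻U (generalized inverse) is referred to a chi-square with
G−1 degrees of freedom, two-sided. All deaths at a tied time are processed
in one step — essential for day-resolution data. The (n+1) denominator
pins the Peto-Prentice variant precisely. Without censoring the weights
reduce to (n_j+1)/(n+1), making the score proportional to the Wilcoxon
rank-sum statistic; the tests exploit this as an independent oracle, along
with lifelines' Peto-weighted log-rank and exhaustive permutation on a toy.
p-values are asymptotic; no permutation fallback is attempted at analysis
scale.

Restricted mean lifespan is the area under the survival curve up to the
last event time (the arithmetic mean when nothing is censored); the q-th
percentile is the first time survival drops to ≤ 1−q.

## Categorical statistics

Fisher's exact test (2×2, two-sided by the minimum-likelihood convention),
Pearson chi-square without continuity correction, and Bonferroni adjustment
min(1, m·p). The ordinal extent-of-loss analysis uses a proportional-odds
cumulative-logit model fit by maximum likelihood (statsmodels), with one
observation per neuron per animal and predictors such as day (numeric),
dorsoventral position, and side; a binary outcome reduces it to logistic
regression, which the tests verify against the closed-form log odds ratio.
Day can equally be coded categorical for pairwise contrasts; both are just
design-matrix choices passed by the caller.

## Power engine

For an empirical lifespan multiset of size n and an observed absent count
k: at each grid correlation, each replicate draws n bivariate-normal pairs
at r = 2 sin(πρ_s/6), ranks both coordinates, labels the k lowest
neuron-span ranks absent, assigns the j-th smallest empirical lifespan to
lifespan-rank j (so the two groups partition the observed multiset exactly,
asserted in tests), and runs the Peto-Prentice test. Power is the fraction
of replicates with p < α (α = 0.05 per test by default; a Bonferroni α/4
mode is available via the `alpha` argument when four neurons are tested as
a family). The union (any-of-four) mode draws one lifespan latent and four
conditionally independent neuron latents per replicate and counts a
detection when any of the four tests fires.

Because the pooled sample never changes across replicates, the pooled event
table, weights and variance core are precomputed once per curve; a
replicate costs one argsort plus O(#distinct days) work, which keeps
5000-replicate, 75-point curves tractable on one CPU.

The default grid has 75 points on [−0.5, 0.5], spaced by a signed-square
rule (denser near 0, where the scientifically interesting thresholds live);
any strictly increasing grid is accepted. The detection threshold at target
power 0.95 is found by averaging powers across matching ±magnitudes,
isotonic regression in |ρ_s| (to tame Monte-Carlo noise without biasing the
crossing), and linear interpolation between the adjacent grid magnitudes;
if the target is never reached the maximum achieved power is reported in
the error. A root seed spawns one deterministic child per grid point, so
any point is re-runnable in isolation; within a point replicates draw
sequentially from one generator.

## Pipeline

`run_independence_analysis` performs, on the animals alive at the
observation day: four per-neuron present-vs-absent Peto-Prentice tests
(one Bonferroni family), four grouped tests — any-missing, number of dorsal
missing, number of ventral missing, total missing — (a second family),
and then the power engine on the cohort's own lifespans with the observed
absent counts, reporting a detection threshold per neuron. Groupings with
fewer than two nonempty groups are skipped with a logged warning. A cohort
is declared independent when no adjusted p-value falls below α. Raw and
adjusted p-values are always reported side by side.

## Problem sizes and numerical choices

The shipped acceptance computation uses 21 uniformly spaced correlation
magnitudes on [0, 0.3] with 500 replicates per point — a grid resolution of
0.015 around the expected thresholds and a Monte-Carlo standard error of
about 0.01 on each power estimate, which the isotonic smoothing and
interpolation absorb; the full 75-point × 5000-replicate design remains the
library default for final analyses. Thresholds computed from the Gompertz
stand-in marginal land near 0.12 for the 3397-animal single-neuron design
and 0.12–0.13 for the 542-animal union design; the residual distance to
values derived from real empirical lifespan distributions reflects the
stand-in marginal, whose tail shape (not just mean and CV) mildly affects
tie structure and hence power. Degenerate inputs are defined away
explicitly: a variance of zero in the test yields p = 1, an all-tied
lifespan multiset gives identical groups regardless of coupling, and
k_absent must lie strictly inside (0, n).

## Known limitations

- Gaussian copula only; families with tail dependence (e.g. Clayton) could
  couple early loss to early death more strongly at equal Spearman ρ.
- Asymptotic chi-square p-values; for very small groups the permutation
  route used in the tests would be preferable.
- The proportional-odds fit relies on statsmodels' general-purpose
  optimizer; complete separation surfaces as a convergence error rather
  than an exact diagnostic.
- Power estimates condition on the observed absent counts k rather than
  re-drawing them per replicate; k is treated as part of the design, which
  matches the conditional question "given what was observed, what could
  this experiment detect?".
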