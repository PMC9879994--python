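# Methods

This note documents the statistical models implemented in `reefmass`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## The size–weight model

For each species, weight W (g) is related to maximum colony diameter D
(cm) by the two-parameter power law μ(D) = a·D^b, under one of two
observation models:

* **gaussian** (default): W_i ~ Normal(a·D_i^b, σ), constant residual
  scale σ in grams;
* **lognormal**: log W_i ~ Normal(log a + b·log D_i, σ), residual scale on
  the log scale — multiplicative errors whose spread grows with the mean,
  which is what real size–weight scatter looks like.

`a` is the weight of a 1 cm colony (g·cm⁻ᵇ); `b` is dimensionless. b = 3
is isometry (mass ∝ length³); b < 3 means large colonies are lighter than
cubic scaling predicts, as is typical when plan-view diameter outgrows
tissue/skeleton depth. The gaussian form is kept as the default because it
is the field-standard formulation for these fits; the lognormal form is
recommended whenever the residual fan shape is visible, and it is the one
used in this package's own validation runs because the generator's noise
is multiplicative. One constant σ per species is assumed; a distributional
(per-observation) σ is out of scope.

Alternative mean functions for model screening: linear μ = a + bD and
exponential μ = a·e^{bD}, under the same observation models.

### Priors

The defaults are weakly informative and fully overridable (`PriorSpec`):

| parameter | prior | rationale |
|---|---|---|
| log a | Normal(0, 2²) | spans ~4 orders of magnitude of scaling constants |
| b (power) | Normal(3, 1²) truncated to (0, ∞) | centred on isometry; prior work on coral size–weight scaling sits well inside ±2 SD |
| σ | half-Normal(s) with s = SD of the response on the fitting scale | scale-adaptive, weak |
| a, b (linear) | Normal centred on the data mean / 0, SD 5× the response SD (per unit of D for b) | analogous weakly informative |
| log a, b (exponential) | Normal(0, 2²); Normal(0, (1/SD(D))²) | keeps e^{bD} in floating-point range over the data |

With n in the hundreds the likelihood dominates all of these; prior
sensitivity shows up only at very small n (the n = 43 species).

### Sampler

Posterior sampling uses an adaptive random-walk Metropolis on
(log a, b, log σ): 4 chains, 5 000 iterations per chain, first half
warm-up (defaults). During warm-up each chain's step size is tuned toward
~30% acceptance (Robbins–Monro) and a pooled empirical covariance sets the
proposal shape (scaled 2.38²/d); adaptation stops at the end of warm-up,
so kept draws form a valid Markov chain. Chains start from the closed-form
log–log least-squares solution plus jitter. Convergence is monitored with
split-R̂ and bulk ESS (via arviz); R̂ < 1.01 on every parameter marks a
converged fit and R̂ ≥ 1.05 raises a warning on the result — never a
silent failure. Correctness is asserted behaviourally (parameter recovery,
agreement with the closed-form oracle at low noise, and a cross-check
against an independent ensemble sampler), not by sampler identity; any
valid posterior sampler could be substituted.

Determinism: every sampling entry point takes a seed and identical inputs
plus seed reproduce draws bit for bit.

### Summaries

Point summaries report posterior mean ± SD (labelled SE), median, and 95%
highest-density intervals. The HDI is the shortest contiguous interval
containing ⌈0.95·n⌉ sorted draws; width ties resolve to the smallest lower
bound. Equal-tailed intervals are available (`eti`). Bayesian R² uses the
residual-variance decomposition R²_s = Var_i(μ_i^{(s)}) /
(Var_i(μ_i^{(s)}) + σ_s²) averaged over draws, computed on the fitting
scale (log scale for the lognormal likelihood).

## Model screening: PSIS-LOO

Pointwise out-of-sample predictive density is approximated by importance
sampling with ratios 1/p(y_i | θ_s). Per observation, the largest 20% of
ratios are replaced by expected order statistics of a generalised Pareto
distribution fitted to their exceedances (Zhang–Stephens posterior-mean
estimator with the standard weak shape regularisation), truncated at the
raw maximum. The shape k̂ is reported per observation; k̂ > 0.7 flags the
estimate as unreliable (a warning attached to the result, not an
exception). Degenerate ratio sets (zero-variance posteriors) skip
smoothing, so elpd reduces to the plain log predictive density.

`loo_exact` refits the model n times, leaving one observation out each
time (guarded at n ≤ 200); it is the brute-force oracle the approximation
is validated against. Comparisons report elpd_diff against the best model
(exactly 0 for the best) with the paired estimator
se_diff = SD(pointwise differences)·√n. Under the lognormal likelihood the
density of W itself (with the log-Jacobian) is used, so elpd values are
comparable across likelihoods.

PSIS is accurate when the model is not grossly misspecified. Fitting the
constant-σ gaussian likelihood to strongly heteroscedastic data drives
k̂ > 1 on high-leverage points and the PSIS elpd can drift more than 1
unit from the exact refits — the diagnostic flags exactly this. The
package's validation therefore screens families under the matched
(lognormal) likelihood, where power-law data select the power family in
every seeded replicate with decisive margins.

## Group comparisons

* **Pairwise location comparisons** ("Bayesian ANOVA"): each group gets a
  Student-t likelihood with its own location μ_g and scale σ_g and a
  shared degrees-of-freedom parameter (ν − 1 ~ Exponential(1/29)). The
  heavy tails keep μ_g close to the group median under the extreme right
  skew typical of per-transect biomass, which is the point of comparing
  "median-like" locations. Each pair is summarised by the posterior median
  difference, its 95% HDI, and the probability of direction
  P(μ_a − μ_b > 0); a difference is called significant when the HDI
  excludes 0. This construction is an interpretation: the published
  analyses this mirrors do not spell out their ANOVA likelihood.
* **Species contrast (ANCOVA-type)**: log W = log a + b·log D + c_s + ε,
  shared (a, b), reference species (alphabetically first) pinned at c = 0.
  Contrasts are reported as multiplicative ratios exp(c_s − c_t) with 95%
  HDI and P(ratio > 1); they are reference-invariant (tested). Placing c
  as an additive log-scale offset is the simplest structure consistent
  with a lognormal ANCOVA and ratio-scale probabilities; note that when
  two species differ in b rather than a, the shared-slope c still absorbs
  the difference over the sampled diameter range — the contrast detects
  "different size–weight relationship", not which parameter differs.
* **Allometry test**: P(b < 3) is the fraction of posterior exponent draws
  below 3, reported with mean ± SE and the 95% HDI.

No multiplicity adjustment is applied beyond reporting all pairwise
probabilities.

## Transect biomass

Frame measurements convert to cm via the scale bar
(cm = pixels × 100·L_ref/pixels_ref). Each coral's weight is predicted
from its species' fitted curve at its maximum length; per-transect,
per-species totals divide by transect area (default 50 × 1 m). Summing
within the transect before dividing by the fixed area is the only reading
of "averaged to the transect level" consistent with a per-unit-area
quantity, and it conserves biomass exactly (density is defined as
total/area). Conventions:

* estimates are emitted only for transects where the species occurred;
* partially visible corals are excluded by default (flag to include);
* point estimates use posterior-mean parameters; a draws mode propagates
  parameter and observation noise into a posterior-predictive 95% HDI per
  coral;
* corals larger than the largest weighed specimen are still estimated but
  flagged as extrapolated, because power-law fits tend to underestimate
  weight beyond the fitted range;
* summaries report mean ± SE, median, min, max and the mean/median ratio
  as a skew diagnostic (sample SE is reported as unavailable at n = 1).

## The synthetic-data generator

The generator exists because the real specimen tables are commercially
restricted. It emulates the statistical structure the analysis assumes:

* **Diameters**: lognormal, truncated to each species' published
  min–max size range, with the log-mean set so the mean diameter matches
  the published per-species mean.
* **Weights**: W = a·D^b·e^ε with ε ~ Normal(0, σ_log²) by default;
  σ_log per species is set so the fits land in the published R² range
  (0.63–0.90). An additive-gaussian option (W = a·D^b + ε, constant σ,
  non-positive draws resampled; σ defaults to σ_log × the mean predicted
  weight) matches the constant-σ gaussian likelihood exactly and is used
  for fitter-consistency checks.
* **Defaults**: exponents 2.2–2.9 (allometric, *C. jardinei* at its
  published 2.73); per-species sample sizes 43–900 matching the published
  counts; scaling constants chosen so predicted weight at the mean
  diameter matches the published mean weight.
* **Transects**: per transect and species, coral counts are negative
  binomial (mean 0.6, size 0.3 by default — most transects empty or
  sparse, occasional crowded ones), 204 transects of 50 × 1 m, depths
  uniform on 0–20.9 m. With small probability (2%) a coral's size is
  inflated 3× to emulate the rare very large colonies that dominate
  per-transect biomass. An optional per-state weight multiplier exists for
  state-effect experiments; no realistic magnitude is assumed for it.

Not emulated: spatial autocorrelation along transects, depth–size
covariance, inter-species co-occurrence structure, measurement error in
diameter, and any real taxonomic or habitat signal. Passing recovery
tests therefore demonstrates that the estimators are correct and
well-calibrated under the assumed data-generating structure — not that
the assumed structure is the true one for any particular reef.

## Problem sizes used in validation

The package's own validation runs use: 50 replicate fits per likelihood at
n = 300 (4 chains × 2 500 kept draws) for coverage and bias; n = 500 at
σ_log = 0.02 for the oracle-equivalence check; an n = 30 fixture for
PSIS-vs-exact LOO (exact refits at reduced draws); 20 replicates for the
family-selection win rate; 50 + 20 replicates for allometry calibration
and power; 100 replicates for the null calibration of the pairwise
comparison; and a full six-species pipeline with 204 transects. These
sizes were chosen to make Monte-Carlo error small relative to the
tolerances being asserted while keeping a full validation run in the
minutes range on a single core.

## Known limitations

* The adaptive Metropolis sampler mixes more slowly than gradient-based
  samplers; ESS per draw is modest (~10%), compensated by cheap
  iterations. Heavily misspecified fits (gaussian likelihood, small n,
  strong heteroscedasticity) occasionally stall below R̂ 1.01 and are
  flagged.
* PSIS-LOO degrades under gross misspecification (see above); the
  Pareto-k̂ flags are the guardrail.
* The species contrast assumes a shared exponent; it ranks species but
  does not attribute differences to a vs b.
* Transect densities use plug-in point parameters by default;
  parameter uncertainty in the density summaries is available only
  through the per-coral draws mode.
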