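# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `cogstab`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Measurement model

Each task x time point is scored as two parallel test halves ("parcels");
the correct-trial sum of a half is an ordinal indicator. Because the sum
scores take few values and are typically skewed, raw sums are collapsed
into ordinal categories before modelling: levels whose marginal relative
frequency does not exceed `min_prop` (default 0.05) are merged inward with
their neighbour, starting from the distribution's tails, until every
category exceeds the floor or only two remain. The merge rule, the floor
and the resulting map are recorded in the output metadata; the rule is a
package construction, exposed as a parameter rather than hard-coded.

Two parcel schemes are available. `alternating` (default) sends odd trial
indices to half 1 and even to half 2, which balances position and
side-counterbalancing schedules. `session_balanced` alternates within
session, so both halves draw equally on both sessions — relevant for gaze
following, whose eight trials come as pairs at the start and end of each of
two sessions. Parallel halves require balanced trial positions; both
schemes conserve the per-cell total correct count, which the tests assert.

Measurement is a normal-ogive graded response model: category `k` of half
`i` has probability `Φ(κ_{i,k+1} − η) − Φ(κ_{i,k} − η)` given the latent
level `η`, with thresholds strictly increasing and invariant across time,
loadings fixed at 1 and error variance fixed at 1. Fixing the error
variance puts `Var(S_t) + 1` in the reliability denominator and identifies
the latent scale.

## Latent state model

`Y*_it = S_t + ε_it` per task x phase, with `S_t ~ N(μ_t, Var(S_t))`,
`μ_1 ≡ 0` as the reference and later means free, so a 95% credible interval
for `μ_t` excluding zero flags a credible change of average ability
relative to the first occasion. `Var(S_t)` is free per time point by
default (an `equal_state_variance` option constrains it); the data do not
identify strong constraints either way, and freeing it lets per-occasion
reliability `Rel_t = Var(S_t)/(Var(S_t)+1)` vary.

## Latent state-trait model

`Y*_it = T + ζ_t + ε_it` with a time-invariant trait `T ~ N(0, Var(T))`
and occasion residuals `ζ_t ~ N(0, Var(ζ))`, equal across occasions, both
shared by the two halves. Trait and residual means are fixed at zero: all
location information is absorbed by the thresholds, because mean change is
the latent state model's job and the LST model addresses variance
structure. Derived draw-wise:

- `Con = Var(T) / (Var(T) + Var(ζ))`
- `OS = 1 − Con` (exactly, per draw — asserted in the tests)
- `Rel = (Var(T) + Var(ζ)) / (Var(T) + Var(ζ) + 1)`

With equal `Var(ζ_t)`, OS is constant across occasions and halves.

The trait may be segmented into blocks of time points (at most two), each
block with its own trait variance and a between-block trait correlation —
the device used when a single stable trait fits a phase poorly (e.g. a
mid-phase ability shift). Candidate misfit is screened by a posterior
predictive check on per-time-point mean category scores: observed means
falling outside the replicated 95% band mark occasions the stable-trait
model cannot reproduce. The check's simulation count and band level are
parameters; it is a screening device, not a formal test.

Pairwise (two-task) models give each task its own thresholds and variance
components, correlate the two traits (bivariate normal), and keep state
residuals and errors independent across tasks. A correlation is flagged
"substantial" when its 95% credible interval excludes zero; the flag is
reported alongside the interval, never instead of it.

## Priors

Thresholds: independent `N(0, 2)` marginals subject to ordering
(parameterized as first cut plus log-increments, with the Jacobian
included). Free state means: `N(0, 2)`. All latent SDs (state, trait,
state residual): half-Normal(1) — weakly informative on the probit scale,
where latent variances above ~9 are scientifically implausible. Trait
correlations: an LKJ(2)-style prior `p(ρ) ∝ (1 − ρ²)`, which is uniform-like
over the interior but regularizes the ±1 boundary where the model becomes
singular. All priors are package defaults, documented here and exposed as
estimator parameters.

## Posterior computation

Latent variables are never sampled. The LS likelihood integrates the state
per subject x occasion with Gauss–Hermite quadrature (default 15 nodes);
the LST likelihood nests a state-residual quadrature inside a trait
quadrature, collapsing, per trait node, the per-occasion category-pair
probabilities into a precomputed table so the cost is linear in subjects,
occasions and nodes. Correlated traits (segmented blocks, task pairs) are
integrated on the product grid reweighted by the bivariate-normal kernel
ratio `φ₂(u,v;ρ)/(φ(u)φ(v))`; accuracy degrades as `|ρ| → 1`, so `ρ` is
capped at tanh(6) ≈ 0.99999 and boundary posteriors are expected to show
elevated R̂ — the convergence gate flags them loudly rather than hiding
them.

Sampling is a metropolized independence sampler: L-BFGS finds the
posterior mode, a finite-difference Hessian gives the Laplace covariance,
and walkers propose from a multivariate-t (df 8, scale 1.1) centred there,
with up to five rounds of moment-matching adaptation to pilot draws while
acceptance is poor. Because the proposal is an independence proposal, the
walkers are genuinely independent Markov chains, so treating walkers as
chains in split-R̂ and ESS (via `arviz`) is exact, and near-Gaussian
posteriors mix almost i.i.d. (acceptance 0.2–0.6 in the fits the suite
runs). Fits fail loudly when any reported parameter exceeds `rhat_max`
(default 1.01); tests that fit many replicates relax or disable the gate
because split-R̂ at a fixed draw budget fluctuates with the BLAS
environment. Everything is seeded; identical seeds give identical
summaries within a process.

The marginal likelihoods are verified against brute-force dense-grid
integration (trapezoid over the latent variables, a method independent of
Gauss–Hermite) to 1e-5 on two-time-point, three-category toys.

## Projection-predictive predictor selection

The reference model is a hierarchical binomial regression of per-occasion
correct counts on all 14 predictors plus a subject random intercept, logit
link, weakly informative priors (coefficients `N(0, 2.5)`, intercept
`N(0, 5)`, random-effect SD half-Normal(1)). Continuous predictors are
standardized; categorical predictors use treatment contrasts (reference
levels: bonobo for group, male for sex, hand-reared for rearing). Two
backends: a Laplace approximation (joint penalized mode with the
random-effect SD updated by moment matching, Gaussian draws from the
curvature) — the default, accurate with ~14 observations per subject and
fast enough for replicated power studies — and full MCMC with the sampler
above, which carries the R̂/ESS contract. The tests show the two agree on
the well-identified coefficients; purely between-subject columns (group,
age) trade off against the random intercepts at 43 subjects and are
weakly identified in either backend — a property of the design, not the
algorithm.

Projection: reference draws are clustered (k-means on fitted
probabilities, default 20 clusters) and each cluster centre is projected by
the trial-weighted maximum-likelihood fit of the submodel to the centre's
fitted probabilities — the KL-optimal projection for the binomial family.
Submodels containing the random intercept keep the subject columns under a
ridge at the reference's estimated `1/σ_u²`. A Gaussian-family variant
(least squares on fitted values; closed form) is provided and is tested
against `lstsq` directly. The forward search adds, at each step, the term
with the largest KL reduction; the random intercept (and optionally a
subject-level time slope) is forced to the last position so that fixed
predictors explain variance first. Per-size elpd and r.m.s.e. use
Pareto-smoothed importance-sampling leave-one-out with the reference
posterior's weights. The search is repeated (default 10 times, different
clustering seeds) and the consensus ranking (mean rank) is evaluated once;
the selected size is the smallest whose elpd is within one standard error
(of the pointwise elpd difference) of the best size among the
predictor-only path — forced terms are part of the final model regardless
and are excluded from the size comparison.

## Synthetic cohort generator

The generator's defaults mirror the study design: 43 subjects (8 bonobos,
two chimpanzee groups of 12 — the split of the 24 chimpanzees into 12/12 is
a package default — 6 gorillas, 5 orangutans); two phases of 14 biweekly
time points (phase starts 2020-08-01 and 2021-05-26); per-time-point trial
counts 8 (gaze following) and 12 (others); delay of gratification in phase
2 only; two sessions on adjacent days with the field-standard task order.
Attrition removes whole subject x time-point blocks at rate 0.18 (first
occasion complete), which keeps per-occasion sample sizes inside the 22–43
band the models must tolerate.

Ability structure: per task, trait variance and state-residual variance on
the probit scale. Defaults encode a reliable, trait-dominated task
(`Var(T)=2.4`, `Var(ζ)=0.6`, i.e. Con 0.8, OS 0.2, test-half Rel 0.75) for
four tasks and a noisy-but-consistent one for quantity discrimination
(`Var(T)=0.95`, `Var(ζ)=0.05`: Rel 0.5, Con 0.95) — the qualitative pattern
a battery like this produces. Task intercepts give low gaze-following
rates, near-ceiling direct causal inference and intermediate levels
elsewhere.

Two modes: `parcel_latent` draws `Y* = T + ζ_t + ε` and cuts it at fixed
thresholds — the exact generative mirror of the LST measurement model, used
for sharp parameter-recovery tests; `trial_level` draws Bernoulli trials
with `P(correct) = Φ(α_task + T + ζ_t + x'β)` — realistic data for which
the ordinal model is an approximation, and the only mode in which the 14
predictor effects act. The predictor diary emulates the variation structure
of each category (stable per subject; AR(1) or Bernoulli per occasion;
group-shared; arrangement-specific); its distributions are documented
defaults, not estimates of any real colony. Power studies use
within-subject-varying active predictors (observer presence, sociality,
rank) because purely between-subject signals are partially absorbed by the
subject random intercept and the collinear group/age block at n=43 — with
only five groups and stable predictors constant within subject, that
confounding is a property of the design the generator reproduces.

What passing tests show — and don't: recovery tests in `parcel_latent` mode
validate the estimators under their own assumptions; `trial_level` tests
add binomial trial noise but still use normal traits, AR(1)-stationary
predictors and missingness-completely-at-random attrition. Real data can
violate all three (heavy-tailed abilities, informative dropout, calendar
irregularities); the descriptives and the posterior predictive check are
the tools that would surface such misfit, not the recovery tests.

## Problem sizes and runtime choices

The suite fits models at n = 43–200 subjects, 6–14 time points, with
1,500–2,000 kept draws (thinned) per fit; replicated studies (consistency
recovery, null false-flag rates, selection power) use 6–20 replicates.
These sizes make each fit take seconds and keep the full suite and the
acceptance script comfortably reproducible on a single CPU while leaving
the Monte-Carlo error of each asserted proportion well below the asserted
margins. `scripts/acceptance.py` runs everything at the study's design
size (43 subjects, 14 occasions).

## Known limitations

- Trait correlations near ±1 sit at a reparameterized boundary: estimates
  are stable but R̂ inflates and the convergence gate triggers; treat such
  fits as boundary diagnoses rather than precise interval estimates.
- The LST model assumes equal state-residual variances and no
  autoregression in `ζ_t`; temporal decay of retest correlations beyond
  what a stable trait implies is visible in the descriptives but not
  modelled.
- The Laplace reference model conditions on the converged random-effect SD
  rather than integrating it; its coefficient intervals are mildly
  optimistic relative to full MCMC (the MCMC backend exists for when that
  matters).
- Split-half reliability is reported for test halves; full-test reliability
  is higher (Spearman–Brown), and no correction is applied.
- At 43 subjects and five groups, group, age and the random intercept are
  partially confounded for any method; selection results for stable
  individual predictors should be read jointly, not coefficient by
  coefficient.
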