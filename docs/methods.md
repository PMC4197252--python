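# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a user re-deriving results
should know about.

## Data transformations

**Cohort.**  One row per patient: area id, categorical covariates,
survival time in years `r > 0` (same-day deaths are excluded upstream) and
an event flag.  Follow-up is administratively truncated at `max_years`
(default 5): a death after the cut-off counts as a censoring at 5 years,
while a death at exactly 5.0 years is still a death in interval 5.
Intervals are right-closed years — interval *t* covers `(t-1, t]`, so a
death at `r = 2.4` happens "during the third year".

**Person-period expansion.**  A patient contributes
`k = min(ceil(r), max_years)` rows.  The binary response is 0 everywhere
except the final row of a within-follow-up death.  This file feeds the
discrete-time logistic model; year dummies `D1..D5` carry the baseline.

**Stratum aggregation.**  For the Poisson model each patient contributes
their *exact* within-interval exposure `min(r, t) − (t−1)` to person-time
and one death to the interval containing `r`, then rows are summed over
covariate pattern × interval × area.  Exact (rather than whole-year)
exposure is the standard piecewise-exponential construction and is what
makes the aggregated likelihood *identical* to the individual-level one —
a property the test suite asserts by aggregating with one patient per
stratum.  Strata with zero person-time are dropped (the offset is
undefined there).

## Multilevel discrete-time model

Bernoulli likelihood on the person-period file with
`logit(h) = β₀ + year dummies (reference year 1) + x'β + u_j`,
`u_j ~ N(0, σ²_u)` independent across areas.  The intercept-plus-dummies
parameterisation is mathematically equivalent to five free `f_t` values
and mixes better with centred covariates.  Priors: improper flat on all
fixed effects and Gamma(shape 0.1, scale 1000) on the precision
`τ_u = 1/σ²_u` — the documented defaults of mainstream multilevel MCMC
software.  (The shape–scale reading is deliberate: it is the only one
whose implied precision moments match the values those packages print.)

Sampling: identical (design row × area) person-period rows are collapsed
to binomial counts first — the likelihood depends only on those totals,
and this makes a 20,000-patient fit take under a second per thousand
iterations.  Updates per sweep: one joint random-walk Metropolis step for
the fixed effects (proposal covariance from the logistic-regression mode,
found by the package's own Newton iteration), simultaneous per-area
random-walk steps for all `u_j` (valid because the `u_j` are conditionally
independent given β and σ²_u), and a conjugate Gibbs draw
`τ_u ~ Gamma(0.1 + J/2, 1/1000 + Σu²_j/2)` (shape–rate).  Proposal scales
adapt towards 30–35% acceptance during burn-in only, so the retained
chain is a fixed-kernel Markov chain.  Everything is deterministic given
the seed; areas with no patients keep prior-only random effects.

**Summaries.**  MOR point estimate from the posterior median variance,
CrI from the per-draw MOR (the transformation of the variance posterior).
An approximate Wald χ²(1) test of `σ²_u = 0` from the posterior mean and
SD is reported alongside — it is a rough frequentist gloss on a
positively-constrained parameter and should be read qualitatively.

## Bayesian spatial model

Poisson likelihood on the stratum table with
`log μ = log y + α_t + x'β + u_j + v_j`.  `α_t` are five free
time-interval intercepts (diffuse `N(0, 1000²)`, like the other fixed
effects).  `v_j ~ N(0, σ²_v)` exchangeable.  `u` has the intrinsic CAR
prior with binary contiguity weights: density
`∝ exp(−(τ_u/2) Σ_{j<k} ω_jk (u_j − u_k)²)`, improper with rank
`J_non-island − C` (one constant per connected component).  The
normalising constant is omitted except the `((J−C)/2)·log τ_u` term the
precision updates need.  Sum-to-zero is enforced per component after
every sweep; islands (areas with no neighbours) are excluded from the
quadratic form and pinned at `u = 0` with the unstructured term carrying
their heterogeneity.

Default hyperprior: Gamma(shape 0.1, scale 100) on both precisions
(precision mean 10, variance 1000).  The five-setting sensitivity grid
(`HYPERPRIOR_GRID`) also offers Gamma(0.5, 1000), the asymmetric
Gamma(0.1, 10)/Gamma(0.001, 1000) pair, and Uniform(0, 10) / Uniform(0,
1000) on the standard deviations (handled by random-walk Metropolis on
log σ).

Updates per sweep: joint Metropolis for (α, β) with a mode-based proposal
covariance; blocked per-area Metropolis for `u` over a greedy graph
colouring (areas of one colour share no edges, so their ICAR full
conditionals are mutually independent and a whole colour class can be
updated at once — two classes on a rook lattice); simultaneous per-area
Metropolis for `v`; conjugate Gibbs for the precisions,
`τ_u ~ Gamma(a₀ + (J−C)/2, r₀ + Σ_{j<k}(u_j−u_k)²/2)` and
`τ_v ~ Gamma(a₀ + J/2, r₀ + Σv²/2)`.

**Initialisation.**  The chain starts `u` at shrunken crude area-level
log-SMR residuals (observed/fitted deaths under the fixed-effects mode)
rather than at zero.  A cold start biases short chains toward too-small
spatial variance, because the random-walk amplitude of a J-dimensional
field grows slowly; the warm start removes that transient.  σ²_u starts
at the empirical variance of the initial field.

**Summaries.**  The spatial fraction uses the *marginal* spatial variance
— the per-draw empirical variance (ddof 1) of the realised `u` vector
over non-island areas — not the conditional ICAR parameter; the
conditional and marginal variances differ by a graph-dependent factor
(`icar_marginal_factor` computes it as the mean diagonal of the
generalised inverse of `D − W`).  Total area-level variance is marginal
spatial + unstructured, per draw.  Smoothed RR is `exp(u_j + v_j)` —
both terms are area-level residuals — with per-area posterior medians and
95% CrIs, sorted for caterpillar plots.

## Diagnostics

**Geweke.**  `z = (m_first − m_last)/√(S_f(0)/n_f + S_l(0)/n_l)` with
windows 10%/50% and spectral density at zero estimated by a
Tukey–Hanning lag window of width 4% of the segment length.  Flag:
non-convergence when the two-sided p < 0.01.  Under an iid null the
p-values are approximately uniform (asserted by a KS test across 200
replicates).

**DIC.**  `DIC = D̄ + pD`, `pD = D̄ − D(θ̄)`, with `D(θ̄)` evaluated at
the posterior mean of *all* sampled parameters including the random
effects — the convention of the MCMC engines this methodology grew up
in.  Because spatial smoothing borrows strength across areas, pD is
routinely far below the nominal parameter count.  Differences between
nested models are read qualitatively: ≥ 7 clearly better, 3–5 weakly
distinguished.

## Synthetic-cohort generator

The generator emulates the statistical structure of a registry cohort of
~22,700 patients over ~478 contiguous areas: a rook-contiguity lattice
map (480 = 20 × 24 areas by default — the closest convenient lattice),
patients assigned to areas uniformly, categorical covariates drawn
independently from published-style frequency tables (area-level
covariates assigned per area and inherited by residents), area frailties
split into an ICAR draw (sampled by spectral decomposition of the
constrained precision) and independent normals, annual Bernoulli deaths
with `logit(h_t) = f_t + x'β + u_j + v_j`, uniform death times within the
year, optional exponential random censoring, and administrative
censoring at five years.  Default effect sizes are the logs of the
published fully-adjusted odds ratios; default calibration targets the
published 58.1% five-year all-cause survival.

Baseline calibration solves `E[(1 − expit(f + L))⁵] = target` over the
full linear-predictor distribution by 1-D root finding (fixed internal
Monte-Carlo sample, residual < 1e-8).  A plug-in variant using only the
mean linear predictor is kept (`method="mean"`); it coincides with the
default when the linear predictor is degenerate but overshoots survival
noticeably when covariate effects have the spread of a real cohort.

Poisson-scale generative effects are set equal to the logit-scale ones:
with annual hazards below ~0.1 the two scales nearly coincide, and the
residual discrepancy is itself the surface the OR-vs-RR concordance
tests measure.

What the generator does **not** emulate: real geography (lattice, not an
administrative map), correlation between covariates, covariate-dependent
censoring, and relative-survival (expected-mortality) structure.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated generative model, not robustness
to the messiness of real registry data.

## Problem sizes and test-time settings

Chains default to desk scale — 5,000/10,000 burn-in and 10,000/20,000
retained draws for the multilevel/spatial backends, a deliberate
package-level choice (production-scale runs of this class of model use
hundreds of thousands of iterations; those settings remain available
through the fit arguments).  The test suite runs smaller still: recovery
experiments use 100 areas × 20,000 patients with ~1,500–3,000 retained
draws, which is enough for the 2-posterior-SD and CrI-coverage checks it
makes.  The hyperprior sensitivity experiment uses a study-sized map
(480 areas, 22,727 patients) with marginal area variances 0.2/0.1 —
"well-informed" data in the sense that the likelihood dominates the
variance hyperpriors.  At small variances (e.g. marginal 0.018/0.006 on
100 areas) the split between spatial and unstructured components is
genuinely weakly identified and the posterior spatial fraction remains
visibly prior-sensitive no matter how long the chains run; this is a
property of the convolution model, not of the sampler, and is the reason
the insensitivity claim is only made for well-informed data.

## Numerical choices and edge cases

- Bernoulli/binomial log-likelihoods use `log1p(exp)` via
  `logaddexp(0, η)`; Poisson log-likelihoods include the log-factorial
  terms, so values are comparable across parameterisations.
- Newton mode-finding with step halving; proposal covariances get a
  `1e-12` diagonal jitter before Cholesky.
- Adaptation uses a Robbins–Monro step `min(0.1, 10/t)` toward 30%
  (blocks) / 35% (scalar fields) acceptance, burn-in only.
- Ties: survival times at integer years belong to that year's interval;
  `r = 5.0` with an event is a death in interval 5.
- Degenerate inputs raise: empty tables, no events, non-positive
  person-time, zero-edge graphs for the ICAR, constant chains in the
  Geweke test, both-zero variance draws in the spatial fraction (dropped
  with a warning when only some draws are degenerate).
- Multiple chains get independent seed streams via `SeedSequence` and are
  concatenated; a single chain is exactly reproducible from its seed.

## Known limitations

- The Wald test on a variance is a crude approximation (kept because the
  methodology's tables report it); the CrI is the better summary.
- ICAR islands are pinned to zero rather than modelled; maps with many
  islands shift heterogeneity into the unstructured term.
- The spatial backend's u/v decomposition is weakly identified on small
  maps with weak signal (see above); report Ψ with its CrI, never alone.
- No relative-survival (expected-mortality) version, no spatial clustering
  test, no INLA-style approximation — out of scope by design.
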