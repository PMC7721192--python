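# Methods

## Model

`tagmove` estimates annual movement among fishery management units from
tag-release/tag-recovery tables, jointly with survival, exploitation,
gillnet selectivity and length-based age composition.

**Cohort propagation.** A cohort is a group of fish tagged at age `a` in
year `ty` and region `tk`. Within each calendar year events happen in a
fixed order: the fish moves first (one draw from the row `π[a, y, k, ·]` of
the annual movement matrix), then is exposed to a full year of competing
instantaneous mortality — fishing at rate `s_a F[k, y]` and natural at rate
`M`. Survival is `S = exp(−s_a F − M)`; the probability of dying to the
fishery is the Baranov fraction `u = s_a F/(s_a F + M) · (1 − S)`. A
harvested fish is reported with the fixed scanning probability
`λ[y, k]`. Ages advance at year boundaries and are capped at an absorbing
plus-group (age `n_ages`+): the terminal age class keeps its own rates for
every subsequent year. The recovery-probability tensor
`P[a, ty, tk, fy, fk]` is accumulated by iterative vector-matrix
propagation of a presence row-vector, one calendar year per step, never by
forming symbolic matrix products; all release cohorts are advanced together
so the cost is linear, not quadratic, in the number of study years.

**Event-order assumptions.** Movement-first means recoveries in the release
year already reflect one movement step. The `AYc` configuration replaces
the release-year movement row by a corrected row in which off-region mass
is scaled by `ratio` ∈ (0, 1) and the stay-probability absorbs the rest —
a one-parameter model of partial dispersal in the truncated first year.
The correction applies to every release cohort with a single shared
`ratio`, only at the release-year step.

**Age composition.** Ages of tagged fish are never observed; each length
class `l` carries a simplex state variable `κ_l` over age classes, with the
aged subsample `n_l` multinomial given `(κ_l, N_l)`. Stratum-level recovery
probabilities mix `P` over `κ_l`. `κ` is a full model unknown updated
jointly with the tagging likelihood; a `plugin_kappa` mode freezes it at
its conjugate Dirichlet posterior mean for fast runs. The Dirichlet(1)
prior per row is realised by normalising Exponential(1) weights, the same
construction used for movement rows, which keeps every sampled parameter
positive and unconstrained after a log transform.

**Likelihood.** Each release stratum `(ty, tk, l)` is one multinomial
observation over its recovery cells `(fy, fk)` with `fy` from `ty` through
the final study year, plus the complementary never-recovered cell
(right-censoring at the study horizon). The multinomial coefficient is
constant in the parameters and omitted. A zero-probability cell holding a
positive count yields an infinite negative log-likelihood, returned rather
than raised so the sampler simply rejects. The convention `0 · log 0 = 0`
applies to empty cells.

## Movement configurations

All seven build row-stochastic matrices by normalising positive weights
`γ` (a Dirichlet-by-normalisation construction; iid gamma(1,1) =
Exponential(1) priors make each row's prior flat on the simplex). The full
`K x K` weight set is sampled; the scale redundancy of each row is absorbed
by the prior rather than pinning one entry. Configurations:

| kind | weights | extra parameters |
|------|---------|------------------|
| C    | one `K x K` set | — |
| YF   | per year | — |
| YR   | per year, `log γ_y ~ N(log ψ, τ)` | `ψ`, `τ` |
| AF   | per age | — |
| AR   | per age, `log γ_a ~ N(log φ, ω)` | `φ`, `ω` |
| AY   | per age-year, nested `log δ_a ~ N(log φ, ν_a)`, `log γ_{a,y} ~ N(log δ_a, ν_y)` | `φ`, `δ`, `ν_a`, `ν_y` |
| AYc  | AY + release-year correction | `ratio` |

`τ, ω, ν_a, ν_y` are standard deviations on the log scale with Uniform(0,1)
priors; `ratio` is Uniform(0,1). Regions that release no fish (MU3 in the
packaged tables) still carry full movement rows — immigrant cohorts pass
through them in multi-year propagation.

## Priors

Per region-year fishing mortality `F ~ U(0, 1)`; natural mortality
`M ~ U(0.2, 2)` — deliberately wide above the assessment value 0.4 because
the study area is open and out-of-system fishery losses load onto `M`;
selectivity inflections `η₁, η₃ ~ U(1, 6)` and slopes `η₂, η₄ ~ U(0, 10)`
for the double-logistic dome `s'_a`, standardised so `max s_a = 1`.
Reporting rates are fixed data, not parameters.

A consequence worth stating as a property, not a bug: with `λ` fixed, `M`
is confounded with any unmodelled loss (emigration out of the study area,
unreported fisheries, tag shedding). On data simulated with external
losses the `M` posterior is biased upward; it estimates "all mortality not
attributable to the modelled, reported fishery".

## Sampling

The posterior is sampled by adaptive random-walk Metropolis on transformed
coordinates (log for positive parameters, scaled logit for bounded ones;
Jacobians included so priors stated on the natural scale remain correct).
Updates cycle over parameter blocks — movement weights, movement
hyperparameters, `F`, demography (`M`, `η`), age-key weights — plus one
joint full-vector proposal that picks up cross-block ridges (`M` vs `F`,
selectivity vs age key). Each block's proposal is multivariate normal with
a covariance learned during burn-in (Welford accumulation, Cholesky
refreshed every 25 updates) and a Robbins-Monro-tuned global scale
targeting 0.44/0.234 acceptance for scalar/vector blocks. The
double-logistic selectivity parameters have strongly curved, sometimes
multimodal conditionals on which Gaussian random-walk moves stall; every
tenth iteration `M`, the four `η` parameters (and, on compact frames, the
few `F` coordinates) are additionally updated by univariate stepping-out
slice sampling, which traverses those conditionals without tuning.
Adaptation freezes at the end of burn-in, so the post-burn-in chain is a
fixed kernel.

Chains initialise from independent prior draws; a budgeted quasi-Newton
ascent (L-BFGS, default 4,000 evaluations) then moves each chain from the
far prior tails into the high-density region before adaptation starts.
This is part of burn-in, not of the kept sample; chains keep distinct
starting points. Without it, covariance adaptation learns transit noise
rather than posterior geometry and short chains understate movement
probabilities toward the uniform prior.

Defaults: 5 chains, 50,000 iterations, 50% burn-in, thinning 10, seed
mandatory. Convergence is monitored by the classic multi-chain
Gelman-Rubin statistic on the sampling scale with the conventional 1.1
threshold; non-convergence flags a run but never discards it. Parameters
with (numerically) zero within-chain variance report an undefined rhat.

## Model comparison

All three criteria are reported on the deviance (−2 log) scale, so
differences between models are directly comparable.

* **DIC** = `D̄ + p_D` with `p_D = D̄ − D(θ̄)`; `θ̄` is the posterior mean on
  the sampling (transformed) scale, which respects parameter support. A
  negative `p_D` — a known DIC pathology under poor mixing or strong
  non-normality — is reported with a warning.
* **WAIC** = `−2(lppd − p_W)` with the variance-form penalty
  `p_W = Σᵢ var_s log p(yᵢ|θ_s)`.
* **PSIS-LOO**: per-observation elpd via Pareto-smoothed importance
  sampling of the inverse pointwise likelihoods (smoothing delegated to
  `arviz.psislw`, which implements the published generalized-Pareto tail
  fit and truncation); observations with shape `k > 0.7` are counted and
  reported.

The pointwise observation unit is one release-stratum multinomial,
mirroring the likelihood factorisation; a per-fish categorical
decomposition is available (`pointwise="fish"`) and sums to the same total.

## The simulator

`simulate_study` generates studies with exactly the statistical structure
the model assumes — multinomial age-at-length, yearly movement, exponential
survival with dome selectivity, Bernoulli harvest and scanning, final-year
right-censoring — in two independent modes: `categorical` draws stratum
fates from the closed-form cell probabilities, `trajectory` walks cohorts
year by year through move/harvest/report events. Their statistical
agreement is the sharpest check on the propagation engine, and the
trajectory oracle in the test suite is a third, package-independent
implementation.

What the simulator does *not* emulate: tag shedding and tagging mortality
(the model assumes none), sex-specific movement, within-year movement
timing beyond the `AYc` correction, environmentally driven year effects,
and length growth across years (the age-length key is pooled, not
year-stratified). Passing recovery tests therefore demonstrate correctness
of the estimator under its own assumptions, not robustness to their
violation.

`lake_erie_like_truth()` fixes the simulation design to the published
study: the actual per-year release sizes from MUs 1-2, the published
scanned-catch reporting rates, `M = 1.36` (the study-scale posterior
median), moderate fishing mortality `F = 0.3`, a dome selectivity peaking
at ages 4-5, and a young-skewed age composition typical of a heavily
exploited percid stock. These are fixed study conditions, not tuning
knobs.

## Scales used by the tests and the acceptance script

Chosen once as desk-scale versions of the study design:

* engine-vs-oracle: 3 regions x 3 years, 10⁶ simulated fish, every cell
  within 3 Monte-Carlo standard errors;
* parameter recovery: constant-movement truth, 3 regions x 5 years,
  20,000 releases per region-year, 10 replicates, 2 chains x 4,000
  iterations — 90% CI coverage and mean absolute bias of movement
  probabilities are scored;
* model selection: sedentary-young / mobile-old truth (two length classes
  with contrasting age compositions to make age informative), Models AR
  and C fitted per replicate with 2 chains x 3,000 iterations;
* PSIS-LOO validation: 20 release strata on a compact 2-year frame (kept
  small so each leave-one-out refit can afford 2 chains x 10,000
  iterations; Monte-Carlo error of the brute-force reference shrinks with
  chain length), each brute-force step refitting the posterior without one
  stratum and scoring its predictive density.

Short chains at these scales do not pass the 1.1 rhat bar for every
nuisance parameter (selectivity parameters mix slowest); runs are flagged
accordingly. Movement probabilities — the quantities scored — are stable
well before the slowest nuisance directions.

## Numerical choices

* Movement rows renormalise exactly once (weights are strictly positive by
  construction); row sums are asserted to 1e-12.
* `log(0) · 0 ≡ 0` in every multinomial term.
* Degenerate selectivity (numerically all-zero `s'`) is rejected and the
  proposal discarded.
* Fate-probability identities (`at-large = 1 − Σ recovery cells`) are
  asserted at construction, tolerance 1e-9.
* The release-year correction keeps rows on the simplex for any
  `ratio ∈ (0, 1]` by construction.

## Known limitations

* The packaged Lake Erie tables are length-pooled (the study's per-length
  release records and 131,469-fish aged sample are unpublished), so fits
  to the packaged data cannot reproduce the original study's posteriors;
  per-length structure is exercised through simulation.
* Random-walk MCMC on the saturated AY/AYc configurations (hundreds of
  latent weights) needs long chains; the sampler contract allows swapping
  in gradient-based backends.
* DIC's point-estimate plug-in makes it the least reliable of the three
  criteria here; WAIC and PSIS-LOO agree with each other far more closely.
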