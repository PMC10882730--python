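# Methods

This note records the models, priors, numerical choices and the design of
the synthetic-data generator, and what the validation suite does and does
not establish.

## Stage one: spatio-temporal adjustment of population denominators

The observation model is log-Gaussian rather than Poisson: area-year
register counts are in the hundreds-to-thousands, where the log-normal
approximation is accurate and buys conjugate updates. Covariates are an
intercept, the log routine register count, a linear time index 1..T+1 and
the proportion of the area's registered population at a practice outside
the data-sharing agreement. The random-effect field `S` follows a
first-order autoregression across years, conditioned in reverse time
order (most recent year marginal-free, each earlier slice conditioned on
its successor) because retrospective extraction makes recent data the
most accurate; each innovation is a Gaussian Markov random field with
Leroux precision `Q(ρ_S, W) = ρ_S(diag(W1) − W) + (1 − ρ_S) I`, which
interpolates between independence (ρ_S = 0) and the intrinsic CAR limit
(ρ_S = 1, singular).

**Priors.** β ~ N(0, 10⁵) independently; σ², τ² ~ Inverse-Gamma(1, 0.01);
ρ_S, ρ_T ~ Uniform(0, 1). These are standard weakly informative choices
for CAR models of this type.

**Sampler.** β, σ², τ² and each time-slice `S_t` have conjugate Gaussian /
inverse-gamma full conditionals and are Gibbs-updated. All `S` algebra is
done in the eigenbasis of the graph Laplacian `diag(W1) − W`, computed
once: every precision encountered is `a·Q + b·I`, which is diagonal in
that basis, so a slice update costs one N×N matrix–vector product instead
of a fresh Cholesky, and the ρ_S log-determinant is a sum of logs of
affine functions of the fixed eigenvalues. ρ_S and ρ_T use random-walk
Metropolis on the logit scale with step sizes adapted toward 44%
acceptance during burn-in (window of 50, multiplicative update); a ρ_S
proposal that would make the precision singular (the intrinsic limit) is
rejected outright. Missing log-counts are redrawn each iteration from
N(x'β + S, σ²); the retained draws are the posterior-predictive sample
used by the adjustment. Defaults are 20,000 iterations, 10,000 burn-in,
thinning 10, one chain; every run is reproducible from its seed.

**Identifiability.** No sum-to-zero constraint is placed on `S`: the
Leroux prior with ρ_S < 1 is proper, and the resulting collinearity
between the intercept and the field mean is accepted — intercept
intervals are wide, slope and variance parameters are unaffected (the
recovery suite covers all of them).

**Adjustment.** `R̂ = R_cdw/P_cdw × P_nhs` holds the register prevalence
fixed, assuming the population the warehouse assigns to a cell is
representative of the true registered population. For observed cells the
adjustment is deterministic; for missing cells each retained draw
supplies its own `P_nhs`, so the denominator is a posterior sample, not a
point estimate. Cells with `P_cdw = 0` are an error: prevalence is
undefined there.

## Stage two: Poisson random-intercept referral model

Percent covariates enter on the 0–100 scale so each coefficient is a
per-percentage-point log rate ratio; study year is a factor with the
first year as baseline (a linear trend would average away the
year-specific intervention signal); the coverage main effect is computed
for all years, pre-intervention included, to absorb baseline differences
between eventually-covered and never-covered areas. Random intercepts are
independent N(0, κ²) — exploratory work behind the source analysis found
no support for a spatial prior here, and the offset already carries the
spatial structure of the denominators.

**Priors and sampler.** γ ~ N(0, 10⁵), κ² ~ Inverse-Gamma(1, 0.01). γ is
updated as a single block by random-walk Metropolis whose proposal
covariance is the inverse Fisher information of a fixed-offset Poisson
regression (computed once at the median offset), scaled adaptively from
2.38/√d toward 23% acceptance; with 21 correlated columns an
unpreconditioned walk mixes far too slowly. Each `Z_i` has a univariate
random walk; the conditionals are independent across areas so all N
proposals are evaluated and accepted/rejected in one vectorised pass
(target 44%). κ² is conjugate. Defaults: 30,000 iterations, 10,000
burn-in, thinning 10.

**Offset resampling.** With a stage-one draw store, a draw index is
re-selected uniformly at random every iteration and the offset
recalculated before likelihoods are evaluated, so each stage-one draw is
represented with equal weight and the chain spreads over the mixture of
fixed-offset posteriors — multiple-imputation semantics. Two details
matter. First, the index stream uses its own generator (`offset_seed`),
so resampling never perturbs the parameter proposals: with a degenerate
draw store the chain is bit-identical whatever the offset seed. Second,
the same freshly drawn offset is used for both sides of each
Metropolis ratio; an alternative that makes the index part of the chain
state and accepts it by Metropolis was evaluated and rejected, because it
reweights the stage-one draws by their Poisson likelihood (the effective
number of represented draws collapsed to ~1% in trials), which is not the
equal-weight propagation intended. The widening contributed by
resampling equals, approximately, the between-draw variance of the
conditional posterior means; when stage-one uncertainty is confined to
two imputed years of a well-identified model it amounts to ~1% of the
interval width — real but below Monte-Carlo resolution of a single pair
of chains — so the propagation test exercises a draw store whose spread
is large enough (per-year and per-cell log-sd 0.1 on the imputed years)
for the effect to be measured reliably.

## Reported summaries

Relative risks are posterior medians of exponentiated coefficients with
equal-tailed 95% intervals (HPD intervals were not used; the posteriors
are near-symmetric and equal-tailed quantiles are exactly reproducible);
significance means the interval excludes 1. Full-intervention effects
combine the coverage main effect with the year's interaction *per draw*,
multiply by the coverage contrast, exponentiate and then summarise —
which is why published percent changes need not equal powers of the
rounded RR table. Interaction-plot predictions fix all other covariates
at their data-set medians and the random intercept at its prior mean 0.
Rounding: RRs to 3 dp, percent changes to 1 dp, per-area averages to
2 dp.

## Synthetic-data generator

The generator is the package's substitute for confidential records; its
defaults are fixed study conditions, not tuning knobs.

* **Scale.** 10×10 queen-contiguity grid (100 areas) by default — large
  enough for spatial structure, small enough for desk-scale MCMC; the
  acceptance script and the figure-reproduction test use 12×17 = 204
  areas with 32 practices, the published study's size. Eight study years
  plus one trailing year used only by stage one; official estimates
  withheld for the first two years.
* **Population.** Area adult populations are log-normal around 1,150
  (the published mean is 1,181, minimum 681) with ~0.5%/year growth.
  Practices have distance-decay catchments (scale 1.2 grid cells), so
  each area is served by a few mostly-local practices; quarterly register
  releases carry 1% log-noise and a practice-level 25+ age fraction in
  [0.65, 0.85]. The official estimate is built from these releases by the
  stated procedure (count × fraction, summed over practices, averaged
  over quarters), so with all error processes off the routine and
  official counts agree exactly up to rounding.
* **Register error.** (i) Two non-sharing practices are removed from the
  routine extract, creating spatially clustered gaps; their population
  share per area is the stage-one covariate. (ii) Retrospective attrition
  multiplies counts by (1−0.02)^(years back) with log-normal noise of
  sd 0.05·√(years back), mixed 0.9/0.44 between a *persistent, spatially
  correlated* area propensity (a Leroux field, ρ = 0.9) and independent
  year noise — areas are consistently over- or under-counted, matching
  the documented pattern of individual areas being wrong in the same
  direction for years. (iii) A per-area fraction (~3%) of the register is
  misassigned to one fixed neighbouring area, constant over time, since a
  wrong address persists for the whole registration spell. The resulting
  median routine-vs-official percent error shrinks monotonically in
  magnitude toward the most recent year.
* **Disease and referrals.** CRD prevalence starts near 8.5% and grows
  ~4.5%/year (matching the published patient-count trend); routine
  patient counts inherit the register distortion through a fixed
  prevalence ratio. Referral counts are drawn from the stage-two model at
  the *true* (undistorted) patient counts with effects set to the
  published relative risks; κ² = 0.023. The intercept is −4.29 rather
  than the log of the published intercept RR because the printed
  intercept is only consistent with the source data's covariate
  distribution; ours is chosen so the implied rate at typical covariate
  values is ~4.5 referrals per 100 patients, the published raw rate.
  Network joiners are practices clustered around a random hub, added
  nearest-first until they reach 50% of the registered population (the
  initiative's reach), which makes area coverage widely spread and
  near-bimodal — as implied by the >50% dichotomisation rule.
* **Determinism.** One seeded generator drives every step in a fixed
  documented order; one seed reproduces a study exactly.

What the generator does *not* emulate: real polygon geography, practice
list churn, within-year seasonality, age-dependent migration, and any
dependence of referral behaviour on unmodelled clinical severity. Tests
passing on these studies show the estimators recover the truth under the
stated error processes; they cannot show the representativeness
assumption behind the prevalence-ratio adjustment holds in real data.

## Validation design

* Exact oracles: Moran's I and the Leroux precision against O(N²)
  explicit loops; a 2-area × 2-year fit with hyperparameters clamped at
  truth against the dense multivariate-normal posterior
  (Kolmogorov–Smirnov on every component of the field).
* Calibration: the permutation test's type-I error at the 5% level
  (500 replicates); posterior-predictive hold-out coverage of an observed
  year's denominators (nominal 95%, accepted range 90–98%).
* Recovery: stage-one (β, σ², τ², ρ_S, ρ_T) and stage-two (all 21 γ, κ²)
  parameter recovery at N = 100, using 5 replicates of 5,000 iterations
  in the test suite — small enough to keep the suite fast, large enough
  that nominal-coverage failures are detectable; the problem sizes used
  are stated in each test.
* The stage-two sampler is additionally checked against a
  maximum-likelihood Poisson regression when κ² = 0 and the intercepts
  are clamped at zero.

## Known limitations

* Stage one has no Poisson variant; very small registers would break the
  log-Gaussian approximation.
* The reported single-chain runs have no cross-chain convergence
  diagnostic; acceptance rates and recovery coverage are the guardrails.
* The two-stage procedure "cuts" feedback: referral data never inform the
  denominator model. This is intended (the adjustment should not be
  contaminated by the outcome) but means the offset mixture is an
  approximation to a full joint posterior, not the posterior itself.
* The prevalence-ratio adjustment assumes register representativeness per
  cell; errors correlated with disease status (e.g. age-selective
  migration) would bias it, and no synthetic scenario here probes that.
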