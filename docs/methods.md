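# Methods

## Data model

The unit of observation is a *sighting*: one identified individual, in one
half-day survey session, at one x/y position (metres), with a behaviour code
(`rest`, `aggressive`, `other`). Multiple fixes of an individual within one
survey collapse to a single presence at the first fix, so a survey
contributes at most one row per individual. Yearly per-individual social
traits are built from these records and carried, together with covariates
(sighting count, years since maturity, social dominance, heterozygosity,
offspring count), in a long yearly-measures table.

## Social metrics

Two individuals are *associated* in a survey when their fixes are within the
association radius (default 1.85 m). The boundary is closed (distance ≤
radius): a deterministic convention, configurable. An association event is
credited to a focal only when the focal's own fix lies inside its 50% core
home range for that year; because the restriction is focal-sided, the two
members of a dyad can accumulate different event sets, and each focal's HWI
is computed from its own events. This ties every metric to the individual's
primary territory while remaining well-defined when only one member's range
is known.

Per dyad and year the counts are: `x` surveys with both seen and associated,
`yAB` both seen but not associated, `yA`/`yB` only one seen. The half-weight
index is `x / (x + yAB + 0.5 (yA + yB))` (Cairns–Schwager form), undefined
(missing) when all counts are zero. Per individual-year and associate-sex
class (opposite-sex vs same-sex, classified by the associate's sex relative
to the focal, so a dyad is OS for both members or SS for both):

* **tendency** — in-core sightings with ≥ 1 event of the class, over all
  in-core sightings;
* **degree** — distinct associates;
* **mean HWI** — mean over the focal's dyads with `x ≥ 1` in the class,
  0 when degree is 0 (a stated convention, not a missing value);
* **social dominance** — proportion of the year's sightings coded
  aggressive.

Social metrics keep individual-years with ≥ 30 sightings; home ranges and
densities require ≥ 25. The two thresholds are independent knobs.

## Home ranges and conspecific density

The utilization distribution is a Gaussian kernel density with fixed
smoothing h (default 7 m, a value previously optimized for this study
system) on a 1 m grid padded 3h beyond the data extent, computed by binning
and Gaussian convolution and normalized to unit mass. The 50% core range
accumulates cells in descending density until the cumulative mass reaches
the level, so the region's mass overshoots the level by at most one cell's
mass and the area error is bounded by one cell per contour step. Point
membership uses the containing cell, not sub-cell interpolation, for bit
reproducibility.

Density is the number of *distinct* conspecifics of the given sex class with
at least one sighting inside the focal's core region that year, divided by
the region's area — individuals per m², which puts values in the 10⁻²–10⁻¹
range for ~10² m² core ranges. Counting individuals rather than sightings
makes the metric invariant to duplicated sightings. The exact numerator and
units of the published quantity are not specified anywhere authoritative;
this definition is a documented package choice.

## The multivariate mixed model

For trait k and row r (an individual-year; an individual for single-measure
traits), the latent linear predictor is

    l_kr = x_kr' beta_k + a_{i(r),k} + u_{t(r),k} + e_kr .

Gaussian traits observe `l` directly. Poisson traits observe
`y ~ Poisson(exp(l))` with `e` an observation-level latent residual
(log-normal overdispersion); without it the latent-scale residual variance
would be undefined. Traits may cover different row subsets (unbalanced
multivariate layout); rows missing a trait are dropped from that trait's
likelihood only, and intercepts are fitted per trait.

Random structures:

* **idh** — per-trait variances, zero covariances, for individual and year
  blocks in repeatability models; the residual block is always idh.
* **corgh** — individual-block variances fixed (to 1 by convention) with
  free correlations, for estimating among-individual correlations. A
  single-measure fitness trait has no within-individual replication, so its
  residual *and* individual variances are both fixed to 1; the only
  estimated fitness-block parameters are its correlations and fixed
  effects.

Priors: scaled inverse chi-square (the univariate inverse-Wishart marginal)
with scale V = 1 and degree of belief nu = 0.002 for random-effect
variances, nu = 0.02 for residuals; effectively flat normal priors
(variance 10⁸) for fixed effects. The correlation block uses a uniform
prior over valid correlation matrices: with nu = 0.002 the
inverse-Wishart's marginal on correlations is effectively flat, so the
uniform prior is the cleaner statement of the same weak information.

### Sampler

A Gibbs sweep with:

* conjugate normal updates for fixed effects, year effects and (under idh)
  individual effects, vectorized over levels;
* under corgh, a joint K-vector update per individual via batched Cholesky
  factorizations of (R⁻¹ + diag(n_ik / V_Rk));
* element-wise adaptive random-walk Metropolis on atanh(r) for the
  correlation matrix, with the tanh Jacobian keeping the prior uniform and
  non-positive-definite proposals rejected;
* scaled-inverse-chi-square draws for unfixed variances;
* element-wise adaptive Metropolis for Poisson latent values (conditionally
  independent given the rest, so proposals are vectorized and accepted
  per observation);
* optionally, a parameter-expansion scale move per unfixed idh variance
  block: a conjugate draw of a redundant multiplier c (prior variance 10³)
  rescales the block's effects and variance jointly, improving mixing near
  zero variance. By construction it leaves the posterior unchanged; the
  test suite checks that posterior mean variance components move by < 0.05.

Initialization: Poisson latents at log(y + 0.5), Gaussian latents at the
observed values, variances at half the sample variance (year at a tenth),
effects at zero, correlations at identity. Step sizes adapt toward 44%
acceptance during burn-in only, so the retained chain has a fixed kernel.
Draws are thinned; all monitored parameters carry effective-sample-size and
lag-1 autocorrelation diagnostics with gates ESS > 1000 and |ac| < 0.1.
Failing gates flags the result as non-converged rather than raising.

## Repeatability

Latent-scale repeatability is applied draw-wise: R = V_I / (V_I + V_R).
The year variance is deliberately excluded from the denominator — this is
*adjusted* repeatability, conditional on year. For Poisson log traits the
observed(count)-scale repeatability uses the log-normal-Poisson moments

    Lambda  = exp(mu + (V_I + V_R)/2)
    V_I,obs = Lambda^2 (exp(V_I) - 1)
    V_P,obs = Lambda^2 (exp(V_I + V_R) - 1) + Lambda,

with mu the trait's intercept (covariates are centred; an
average-over-covariates mode is a one-line change and both conventions give
identical answers for centred designs). The closed form is validated in the
tests against a 10⁶-draw Monte-Carlo variance decomposition (agreement
within ±0.005 across a grid of mu, V_I, V_R). Gaussian traits need no
transformation: latent R is the data-scale R exactly.

Credible intervals default to highest-posterior-density intervals
(quantile intervals by flag); a parameter is "significant" when its 95%
interval excludes zero. Sex contrasts pair permuted draws from the two
independent per-sex chains; pd = max(P(diff > 0), P(diff < 0)) converts to
a two-sided p as p = 2(1 − pd).

## Synthetic data

`simulate_trait_panel` draws directly from the generative model above:
individual effects jointly across traits from a scaled correlation matrix
Omega_I, year and residual effects independent Gaussians, Poisson traits
exponentiated and Poisson-sampled. One measure per individual-year matches
the yearly-measures design; an unbalanced mode keeps each individual in a
random subset of years (at least one), mirroring real panels where not all
individuals are seen every year. `simulate_fitness` attaches one Poisson
count per individual whose log-rate effect b_i has unit variance and a
specified correlation with the (standardized) individual trait effects —
the same fixed-to-1 convention the fitness models use.

`simulate_sightings` generates survey-level data: individuals are detected
with probability 0.8 per survey (chosen so sighting counts straddle the
25/30 eligibility thresholds and the filter logic is exercised), positions
are bivariate normal around fixed home-range centres, and a detected
individual is relocated to within the association radius of a concurrently
detected neighbour with probability sigmoid of the dyad's mean
gregariousness. This reproduces the qualitative structure the pipeline
needs — dyadic proximity associations, sex partition, detection gaps that
drive the HWI denominator — but does *not* reproduce any published metric
distributions: there is no territoriality, avoidance, temporal
autocorrelation in movement, or observer bias. Passing end-to-end tests
therefore demonstrates correctness of the aggregation machinery, not
realism of the movement model, and no distributional facts about real
survey-level detection are claimed.

## Validation scale

Sampler validation uses panels of 200 individuals × 4 years with chains of
5 000–10 000 post-burn-in sweeps thinned to ~1 700–2 000 draws — sizes at
which conjugate-update parameters pass the ESS gate while replicate-based
checks (coverage over 20 repeatability replicates, 12 null-correlation
replicates, 10 fitness replicates) complete in minutes on one CPU. The
paper-scale run lengths (10⁵–10⁶ iterations, thinning 10³) are available
through the same configuration fields; the model is identical.

## Known limitations

* The Metropolis correlation updates mix more slowly than the conjugate
  components; at desk-scale chain lengths correlation parameters can sit
  below the ESS gate and the result is then flagged non-converged even
  though point estimates are already stable. Longer, more thinned runs
  clear the gate.
* No pedigree ("animal model") effects, no zero-inflated Poisson fitness
  (reported elsewhere as non-convergent), no network permutation nulls, no
  cross-validation of the kernel smoothing parameter.
* The dyadic co-occurrence convention (focal-sided core-range restriction)
  is one defensible reading of a convention whose authoritative definition
  is not public; it is configurable at the code level and documented here.
* In fitness models the sighting-count and age covariates enter the
  repeated traits, while dominance and heterozygosity enter the fitness
  trait; which traits receive which covariates is configurable since
  published precedent is ambiguous. Fitness results are reported for OS
  and SS trait sets via two separate models per sex.
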