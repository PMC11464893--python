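# Methods

`habsurv` links where animals choose to breed to how well they fare there.
It couples two hierarchical Bayesian model families over a shared
multi-scale covariate engine, validates both out of sample, and overlays
their spatial predictions into a source-to-sink habitat ranking.  Because
the motivating data (telemetry of a sage-grouse population across
reproductive life stages) are restricted, a synthetic-data module with
known ground truth stands in for them; every claim the test suite makes is
therefore a claim about simulation recovery, not about field data.

## Models

**Resource selection (used/available logistic).** For point *i*,

    logit P(used_i) = b0 + X_i beta + kappa_site + eta_year + nu_animal

with `kappa`, `eta`, `nu` normal random intercepts.  Used points are
telemetry locations; available points are sampled uniformly at a 5:1
available:used ratio within the availability radius — the 90th percentile
(linear interpolation between order statistics, pooled across individuals
by default) of movement distances from the anchor: the lek for nesting,
the individual's nest for brood stages.  Distance to the anchor enters as
a confounder covariate so that central-place movement behaviour is not
absorbed by habitat terms.  The logistic fit is only a device for
estimating `beta`: the RSF itself is `w(x) = exp(X beta)` with intercepts,
random effects and the distance confounder discarded.

**Exposure-time survival.** Encounter histories are interval-censored:
one record per interval between checks, with entry day, exit day, length
`t` and fate `y`, covariates measured at the interval start.  Daily
survival for interval *i* is

    logit DS_i = g0 + X_i beta + kappa_site + eta_year

and the interval likelihood is `y_i ~ Bernoulli(DS_i ** t_i)`.  The
individual-level random intercept is absent from survival models (each
unit contributes a handful of intervals).  Cumulative stage survival is
`DS ** d` with d = 38 (nesting), 21 (early brood) and 28 (late brood)
days; the full 50-day brood period is the product of the two brood terms.

**Priors.** Habitat coefficients get Lasso (Laplace) priors with a single
tuning parameter `lambda ~ Uniform(0.001, 10)` per model, updated by a
Gibbs draw from its truncated-Gamma full conditional.  Random-intercept
spreads have a uniform prior on the *variance*, Uniform(0, 100)
(`variance_prior="sd"` switches to uniform-on-SD).  Intercepts are flat.

**Multi-scale selection (BLISS).** Windowed covariates are computed at
candidate radii tied to movement: 167.9 / 439.5 / 1451.7 m (minimum, mean
and maximum daily movement) for all stages, plus 75 and 260 m for nesting
and 260 / 370 m for early / late brood.  Covariates are organized into 12
groups of correlated variables; each group keeps one coefficient and a
latent categorical indicator naming which variable-by-scale column enters
the linear predictor.  The indicator is Gibbs-sampled from its full
conditional each iteration.  Because the coefficient count never changes,
this is a fixed-dimension sampler; the posterior is identical to the
reversible-jump construction usually cited for BLISS, without
trans-dimensional bookkeeping.  A two-stage workflow mirrors standard
practice: stage 1 runs BLISS over all groups; stage 2 refits a final model
containing each group's modal winner (ties break toward the smallest
radius) as ordinary fixed effects.  Confounders are exempt from BLISS but
share the Laplace prior.

**Sampler.** Metropolis-within-Gibbs: adaptive random-walk updates for the
intercept and each coefficient (step sizes tuned toward ~0.38 acceptance
during burn-in only), vectorized per-level random-walk updates for random
intercepts (levels partition the rows, so acceptance is decided per
level), log-scale random-walk for variances, Gibbs for `lambda` and the
BLISS indicators.  Defaults mirror the study design — 3 chains, 30,000
iterations, first 20,000 discarded, thin 5 — with every setting
configurable; tests and the demo pipeline use much shorter, seeded runs.
The printed retained-draw arithmetic of the source design (10,000 retained
from 30,000 with thin 5 after a 20,000 burn-in) is internally
inconsistent; we implement the rule literally: retained per chain =
(iterations − burn-in) / thin.  Convergence is assessed with the classic
Gelman–Rubin potential scale reduction factor (threshold 1.1); a unit test
cross-checks the implementation against `arviz.rhat`.

**Posterior summaries.** Point estimates are posterior medians.  Relative
selection strength is `RSS = exp(beta)` (relative use intensity of two
locations one covariate SD apart; >1 is selection).  The probability of
direction `pd = max(P(beta>0), P(beta<0))` flags moderate effects at 0.85
and strong at 0.95.  Intervals default to 95%, with 85% also reported.

## Covariate engine

Focal statistics use circular windows with membership decided in metric
units (a pixel belongs when its center lies within the radius of the focal
center), so fractional radii on a 30 m grid are handled exactly; edge and
missing-data windows are normalized by the count of valid in-window
pixels.  Feature density is feature pixels per window pixel — the same
moving average applied to a 0/1 band.  Distance covariates are transformed
as `exp(-d / alpha)` with `alpha` set to the mean raw distance over the
rows of the specific analysis's design table (per-analysis, not per-map).
All covariates are centered and scaled using the *population* (divide-by-n)
SD; the fitted means/SDs are stored and reused verbatim at prediction
time, never recomputed from the map.

## Validation

Fifty individuals (configurable) are withheld whole — never single rows —
before fitting.

* **RSF cross-validation.** RSF scores over the availability domain are
  cut into 10 ranked bins at quantiles of the prediction distribution
  (approximately equal-area bins; equal-interval bins on a skewed RSF
  surface put nearly all area into one bin, whose leverage then dictates
  the regression).  Expected test counts are proportional to each bin's
  total RSF weight; observed counts are regressed on expected.  Reported:
  Spearman's rho between bin rank and area-adjusted observed frequency,
  the regression R², and the slope (1 is ideal, 0 means the model carries
  no information).
* **Used-habitat calibration.** Per posterior draw, test-sized point sets
  are re-sampled from availability with weight `exp(X beta)`; the kernel
  density of each covariate among those simulated used points forms a 95%
  predictive envelope compared against the observed test-point density.
* **Survival posterior-predictive check.** Per draw, fates are
  re-simulated over the test exposure structure (units censored after
  their first simulated failure); the discrepancy is the maximum absolute
  difference between a product-limit survival curve and the draw's model
  curve, and the Bayesian p-value is the share of draws whose replicated
  discrepancy exceeds the observed one.  Values near 0 or 1 flag poor fit.

## Mapping

Selection maps use `HSI = w / (1 + w)` from posterior-median coefficients
(no intercept, no random effects, no distance confounder).  Categorization
is the percent-isopleth method at used locations with cutoffs at the 50th,
25th and 5th percentiles of use: the high class contains the top 5% of
used-point HSI values, so thresholds are the 50th/75th/95th quantiles of
HSI at used points.  Ties at a threshold fall in the lower class.
Survival maps retain the intercept (DS is an absolute probability), are
exponentiated to stage durations, and are categorized from the
distributions of predicted values at failed versus successful units.  The
source design defers the survival thresholds to an external rule we could
not reproduce; the default here is: very-low/low boundary = median at
failed points, moderate/high = median at successful points, low/moderate =
their midpoint, all overridable.  When the two point distributions cannot
be separated (near-flat surfaces), the pipeline falls back to surface
quartiles with a logged warning; the categorizer itself stays strict.

Composites multiply the three max-relativized stage HSI surfaces
(equal stage weights; the composite maximum is exactly 1) and the three
unrelativized cumulative survival surfaces; survival composites are only
evaluated on pixels the composite selection map calls habitat.  The
composite selection surface is re-categorized with the isopleth method at
used points pooled across stages.

**Ranking.** The 3 habitat selection classes × 4 survival classes give 12
cells.  The source design pins only the extremes — high selection + high
survival at the top, high selection + very low survival at the bottom.
The full ordering here: within high or moderate survival, higher selection
ranks better; within low or very-low survival, higher selection ranks
*worse* (stronger attraction to poor habitat is more maladaptive).  Area
summaries report km² (pixels × 900 m²) and percentages under both the
whole-region and habitat-only denominators, since the two conventions
differ and both are useful.

**Management categories.** Given an external binary abundance-and-space-use
(ASUI) raster: priority+ = high selection ∧ high survival ∧ high use;
priority = any habitat ∧ high use, or source habitat (top two ranks)
outside high use; general = high selection with low/no use, or nonhabitat
inside high use; other = moderate selection with low/no use.  Rules apply
in that order.  Computing the ASUI itself is out of scope; the demo
pipeline thresholds distance-to-lek as a stand-in.

## Synthetic data

The generator emulates the study system's structure: spatially
autocorrelated covariate bands (Gaussian random fields by
kernel-convolution of white noise, with configurable range and sill;
land-cover fractions squashed to (0,1); temporal bands share a persistent
base field across years), point and line features (leks, springs,
meandering rasterized streams) with Euclidean distance bands, animals
nested in sites with lek and nest anchors, used points drawn with weight
`exp(X beta_true)` inside each animal's availability disc, and daily
Bernoulli fates observed only at periodic checks.  The availability domain
used for generation equals the one the design stage later assumes, so
recovery tests are well-posed.  All randomness flows from one seed through
named substreams; identical configurations reproduce every artefact
bit-for-bit.

What the generator does *not* emulate: movement trajectories (points are
exchangeable draws, not paths), GPS error, observer effects, disturbance
or detection failure, temporal autocorrelation in fates beyond the daily
hazard, and real land-cover geometry.  Passing recovery tests therefore
demonstrate that the estimators are consistent with their own generative
assumptions — not that those assumptions hold in any field system.

Default conditions follow field-typical values: daily nest survival
0.9749 (0.38 over 38 days), daily brood survival 0.9940 (0.74 over 50
days), selection effects of 0.3–0.8 SD, random-intercept SDs of 0.2–0.3,
10-day check intervals, 30 m pixels.

## Numerical choices and test scales

* Logistic and exposure log-likelihoods use `logaddexp` /
  `log1p(-exp(a))` stable forms; interval failure probabilities are exact
  for any `t`.
* `lambda`'s truncated-Gamma Gibbs step falls back to an inverse-CDF
  power-law draw when all coefficients are zero, and to the nearer bound
  when the truncation interval has negligible mass.
* Non-finite likelihood at initialization triggers re-jittered restarts
  (bounded count) before failing loudly.
* Constant-survival recovery tests use 2000 simulated units so their
  ±0.03 tolerance sits near 3 binomial standard errors; the replicate
  coverage check runs 20 exposure-model fits of 1000 units each with
  shortened, seeded chains.  The demo pipeline runs a 120×120 grid with
  reduced chain lengths; all sizes are configuration, not estimates of
  anything.

## Known limitations

* The sampler is random-walk based; posteriors with strong coefficient
  correlations mix slowly compared to gradient samplers.  The two-stage
  BLISS workflow keeps per-group dimension at one, which mitigates this.
* Focal bands at neighbouring radii are often correlated above 0.95 on
  smooth landscapes, so the BLISS indicator occasionally concentrates on a
  scale adjacent to the generating one; an independent maximum-likelihood
  check confirms that in those realizations the adjacent scale genuinely
  fits better.  Scale identification is a property of the data, not of
  the sampler.
* `PosteriorDraws` stores dense per-chain arrays; very long runs with
  per-level random-intercept storage enabled can be memory-heavy.
* Raster I/O is plain-text ASCII grids; there is no projection handling
  beyond a uniform affine (square pixels, north-up).
* The survival-categorization default is one defensible reading of an
  under-specified rule; sensitivity to it should be checked with the
  `thresholds` override when it matters.
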