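# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `colonywatch`, in the order the pipeline runs
them.

## Study design being emulated

Common guillemots (*Uria aalge*) at a temperate colony reoccupy their
breeding sites through the non-breeding season (October–March).  Two
subcolonies of fixed ~10 cm breeding sites are photographed by time-lapse
cameras every 15 or 30 min during daylight; each image is scored 0, 1, or
2 birds per site.  Site quality is the site's historic breeding-success
proportion.  The analysis asks whether higher-quality sites are occupied
earlier and more intensively (site defense), whether occupancy predicts
the next season's lay date and breeding success, and how much of the
quality effect on success is transmitted along the chain
quality → return date → occupancy frequency → lay date → success.

## Occupancy metrics

For each site-season and presence filter (`any` ≥ 1 bird, `single` = 1,
`pair` = 2):

* **Return date** — first survey day with a matching image at the site.
* **Occupancy frequency** — occupied survey days / survey days from the
  return day to March 31 inclusive.
* **Relative time investment (RTI)** — matching images at the site /
  images with ≥ 1 bird anywhere in the subcolony, summed over survey days
  from the site's return day (ratio of sums).  A per-day mean is exposed
  as an alternative column; the season-level ratio is primary because it
  is what the population summary ("55% of the time the subcolony was
  attended") measures.  The RTI denominator always uses the any-bird
  filter, whatever the numerator filter.

A *survey day* is a day with at least one scorable image for the
subcolony.  Camera outages are excluded from every denominator — an
unscored day is unknown, not empty.  A documented toggle
(`rti_window="season"`) starts the RTI denominator at the season start
instead of the return day.  Sites never occupied in a season keep an
absent return date and are excluded (with a logged count) from models
that need one.

Covariates are standardized within subcolony × season (sample SD, n−1),
and the group mean/SD are retained so effect sizes can be reported in
natural units.

## Mixed models and selection

All hypothesis tests use linear or generalized linear mixed models with
site and subcolony-year random intercepts.  Aggregated binomial responses
(frequency, RTI) are modeled as counts with their recorded denominators
as trials, with a logit link; success is Bernoulli-logit; return date and
lay date are Gaussian.

Estimation is maximum likelihood: exact profiled ML for Gaussian
responses; a first-order Laplace approximation with penalized IRLS for
binomial/Bernoulli responses (the `glmer` approach).  ML rather than REML
is used wherever models are compared, because fixed-effect AIC
comparison is only valid under ML.  For *reporting* a chosen Gaussian
model the package can refit by REML (`fit_mixed(..., reml=True)`): with
three observations per site, ML variance components are biased low and
Wald intervals undercover slightly; REML reporting is the lme4
convention.  REML fits carry a note that their likelihoods must not enter
AIC comparisons.

Model selection fits every sub-model of the fixed structure (closed under
marginality) on identical complete-case rows and applies a two-step rule:
if the AIC gap to the runner-up exceeds 2, the lowest-AIC model wins;
otherwise the most parsimonious model within 2 AIC units is selected,
with ties broken by parameter count and then lexicographic term order —
fully deterministic.  The same rule compares four random structures
(intercept; correlated intercept+slope; independent intercept and slope;
slope only) for the subcolony-year factor.  Covariate pairs with
|Pearson r| > 0.7 on the standardized design columns are flagged and
models containing both members are dropped from the candidate set.

Confidence intervals are profile-likelihood by default for single fits
(Wald fallback with a recorded note); the batch pipeline uses Wald.
Marginal and conditional R² follow the fixed/random/residual variance
decomposition with π²/3 as the logit-scale residual variance.  Gaussian
response normality is checked with a two-sided one-sample KS test against
a moment-matched normal; with estimated parameters this test is
conservative, which is documented rather than corrected.

## Bayesian path analysis

Five fixed pathways, every one starting at site quality and ending at
breeding success:

1. quality → success
2. quality → return date → success
3. quality → lay date → success
4. quality → occupancy frequency → lay date → success
5. quality → return date → occupancy frequency → lay date → success

Each pathway decomposes into single-predictor regressions
`γ = α + β·X + ε_site` with a site random intercept.  Success is
Bernoulli-logit; mediators are Gaussian parameterized by mean and
precision τ.  Priors: Normal(0, precision 0.001) on α and β;
Gamma(shape 0.001, rate 0.001) on every precision (the conventional
minimally-informative reading — a gamma cannot have mean zero, so a
stated zero-mean gamma prior is interpreted as this near-flat form).
Continuous variables are standardized before modeling; the binary
endpoint stays 0/1 because standardizing a Bernoulli response is not
model-coherent.

Sampling is adaptive Metropolis-within-Gibbs.  Gaussian edges draw
(α, β, u) *jointly* from their exact multivariate-normal conditional
(block updates mix slowly when the site variance dominates, because α
trades off against mean(u)), then the two precisions from their gamma
conditionals.  Bernoulli edges use random-walk Metropolis for α, β and
the site-effect vector (three interleaved u/τ sweeps per iteration),
proposal scales tuned to ~44% acceptance during burn-in only, plus an
exact translation move between α and mean(u) that leaves the linear
predictor invariant.  The canonical schedule is 3 chains × 200,000
iterations, burn-in 15,000, thinning 3; a reduced schedule
(3 × 20,000, burn-in 2,000, thin 3) is provided for quick runs and
flagged non-canonical.

Because the five pathways share edges and no parameters cross edges, the
eight unique edge regressions are sampled once and reassembled per
pathway — identical to fitting pathways separately with the same seed.

A pathway coefficient is the product of its standardized edge
coefficients per posterior draw (the classic path-composition rule); the
summary reports the posterior mean, the 2.5–97.5% credible interval, and
the percentage of draws sharing the mean's sign.  The direct coefficient
of the final edge is emitted alongside for transparency.  Convergence is
judged by the classic Gelman–Rubin statistic (acceptance bar 1.05) and an
autocorrelation-time ESS (Geyer initial monotone positive sequence,
summed over chains; bar 400).

## Synthetic-colony generator

The generator is the test bed for everything downstream: it produces
image-score tables whose *measured* metrics carry known effects.

Structure, per subcolony × season:

* **Site quality** ~ Beta(1.3, 0.9), rounded to a proportion of a
  simulated 20–36 breeding attempts (mean ≈ 0.59, SD ≈ 0.27 — the spread
  implied by "one day earlier per 6% of quality" at −4.67 d/SD).
* **Return day** — Gaussian around season-day 56 (Oct 27, counted from
  Sep 1) with a −4.67 d/SD quality effect, a 5-day site intercept, and a
  9.5-day residual (total spread ≈ 11.7 d).  A bird always attends its
  return day; if the colony is quiet that day the visit spans a single
  image, so the measured first-occupancy day equals the latent one
  without polluting the subcolony attendance denominator.
* **Colony-day gate** — a shared "is the subcolony attended today"
  indicator with rate c(d), carrying the seasonal rise to the ~50% daily
  plateau and the early-December / early-February dips.  The gate is what
  lets RTI (time at the site *given* the subcolony is attended, mean
  0.55) exceed occupancy frequency (mean 0.46): without day-level
  correlation the RTI denominator covers nearly every image and RTI ≤
  frequency identically.  c(d) is derived from the configured seasonal
  curve by dividing out the expected returned fraction, then normalized
  so its mean over a site's expected window equals
  mean_freq / mean_rti.  The gate is realized by error-diffusion
  (low-discrepancy) thinning rather than Bernoulli draws: a shared random
  day field would add window-mean noise that no downstream model term can
  attribute, miscalibrating fixed-effect standard errors, while the
  deterministic pattern keeps the seasonal shape and leaves site-days
  conditionally independent.  All-or-nothing colony attendance days are
  themselves realistic for guillemot winter attendance.
* **Site-day occupancy** — on gated days, Bernoulli with probability
  f_s / c̄ where logit f_s = logit(0.46) + 0.82·z_quality + site effect.
* **Image-level presence** — a shared diel gate follows the within-day
  curve (piecewise log-linear rise to a peak 1.5 h after nautical dawn,
  exponential decline to exactly zero at nautical dusk), thinned per site
  by r_s chosen so the season-level RTI is logit-linear in quality
  (0.94 logit/SD) around mean 0.55.  A second bird is present with
  probability 0.5 given presence, enabling the pair/single analyses.
* **Breeding** — lay date is Gaussian (mean season-day 244 ≈ May 2,
  residual 4.7 d, site effect 5 d — this split reproduces the reported
  lay-date variance decomposition, marginal R² ≈ .02 / conditional ≈ .5)
  shifted by −0.93 d per SD of the site's *measured* occupancy frequency;
  success is Bernoulli with logit 0.8 − 0.5·z(measured return day) plus a
  site effect.  Using the measured (post-gap) metrics rather than latent
  ones means downstream fits see no errors-in-variables attenuation.
* **Gaps** — declared unscorable intervals (~10% of days per subcolony,
  default calendar clear of the October return window, where an outage
  would censor first-occupancy dates) remove records entirely; removed
  days are unsurveyed, not zero.
* **Daylight** — nautical dawn/dusk at 56.2°N from the standard solar
  declination/hour-angle formulas (accurate to minutes, far below the
  image cadence); no record exists outside daylight.  A closed-form
  computation replaces a shipped dawn/dusk table: it is smaller, exact at
  any date, and needs no astronomy dependency.

Configured means are logit-scale typical values: under site
heterogeneity the realized population means differ by Jensen-type terms
of a percent or two, and the defaults-on mean RTI sits near 0.51 because
a site cannot invest more relative time than the colony-attendance bound
f_s/c̄ allows (the min() substitutes an almost identically sloped
quality relationship, so recovery of the 0.94 logit/SD effect is
unaffected).

What the generator does *not* emulate: weather or energetic mechanisms
behind the dips (only their shape), individual identity and pair
coordination beyond independent thinning, observer error in image
scoring, and any density dependence.  Passing recovery tests therefore
demonstrates that the pipeline estimates what the generator encodes — not
that real colonies satisfy these structural assumptions.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams per
stage; identical configurations produce byte-identical outputs.  The
test-bench problem sizes: parameter-recovery coverage uses 100 colonies
at the default size (two subcolonies of 27 and 51 sites, three seasons);
the five-pathway convergence check and the acceptance script use one
50-row subcolony-1 analysis table with the reduced MCMC schedule; the
AIC-recovery experiment uses 60 replicates at n = 120 with a 1-SD
effect.  Chains are stored post burn-in and thinning.

## Known limitations

* The Laplace likelihood is first-order: on sparse Bernoulli data its
  marginal log-likelihood differs from brute-force quadrature at the
  1e-4 relative level (it is asymptotically exact as information grows).
* Profile intervals are computed for fixed effects only, and REML
  reporting exists only for Gaussian responses.
* The GLMM engine supports at most two crossed grouping factors plus
  observation-level terms — the designs this pipeline needs, not a
  general formula engine.
* The `%-same-sign` posterior summary is implemented literally; for a
  posterior centered at zero it hovers near 50 by construction.
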