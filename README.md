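# colonywatch

Analysis pipeline for **non-breeding-season occupancy of seabird breeding
sites**: from time-lapse image scores to occupancy metrics, mixed-model
hypothesis tests, and a Bayesian path analysis linking site quality to
breeding success.

Colonial seabirds such as the common guillemot (*Uria aalge*) reoccupy
their cliff breeding sites months before laying.  The site-defense
hypothesis predicts that high-quality sites are occupied earlier and more
intensively, and that this investment pays off in earlier laying and
higher breeding success.  `colonywatch` implements the full analysis a
field team needs to test that prediction from time-lapse scoring records —
and, because such records are rarely public, a calibrated synthetic-colony
generator with known ground-truth coefficients, so every stage of the
pipeline is testable end to end.

## What it computes

**Occupancy metrics** per breeding site and season, from image scores
(one row per site × image, 0/1/2 birds), for any of three presence
filters (≥1 bird, exactly 1, exactly 2):

* *return date* — first survey day the site is occupied;
* *occupancy frequency* — proportion of survey days occupied from return
  to March 31;
* *relative time investment (RTI)* — images at the site over images with
  any bird in the subcolony.

**Mixed models** (own ML engine: exact Gaussian, Laplace
binomial/Bernoulli) with site and subcolony-year random effects,
all-subsets AIC selection under the two-step rule (lowest AIC when the
gap exceeds 2, otherwise the most parsimonious model within 2), profile
or Wald intervals, Nakagawa marginal/conditional R², KS normality checks
and a collinearity screen.

**Path analysis**: five pathways from site quality to breeding success
(directly, or via return date, occupancy frequency and lay date), as
chains of Bernoulli-logit / Gaussian regressions with site random
effects and minimally-informative priors, sampled by adaptive
Metropolis-within-Gibbs (3 chains × 200,000 iterations, burn-in 15,000,
thin 3 by default), with Gelman–Rubin and effective-sample-size
diagnostics and pathway coefficients composed as products of standardized
edge coefficients.

See `docs/methods.md` for models, priors, generator calibration, and
numerical choices.

## Worked example

```python
from colonywatch.simulate import SimulationTruth, simulate_colony
from colonywatch.metrics import occupancy_metrics
from colonywatch.io import build_analysis_table
from colonywatch import glmm as G

colony = simulate_colony(SimulationTruth(seed=1))          # 2 subcolonies x 3 seasons
metrics = occupancy_metrics(colony.image_scores)           # one row per site-season
table = build_analysis_table(metrics, colony.sites, colony.breeding)

fit = G.fit_mixed(
    G.ModelSpec("return_day", "gaussian", fixed=(("quality_z",),),
                random=(G.RandomTerm("site_id"), G.RandomTerm("subcolony_year"))),
    table, reml=True)
print(fit.summary()[["term", "estimate", "lower", "upper"]])
```

prints

```
          term   estimate      lower      upper
0  (Intercept)  55.380342  53.822428  56.938256
1    quality_z  -5.328503  -6.906783  -3.750223
```

i.e. in this synthetic colony the average site is first occupied on
season-day 55.4 (late October, counted from Sep 1), and a one-SD increase
in site quality advances first occupancy by 5.3 days (95% CI 3.8–6.9) —
covering the generator's −4.67 d/SD truth.  The same table drives the
occupancy-frequency and RTI binomial models, the lay-date and success
models, and the path analysis:

```python
from colonywatch.pathmodel import (MCMCConfig, fit_all_pathways,
                                   pathways_table, standardize_path_data)
pdat = table[table.subcolony == 1].dropna(
    subset=["quality", "return_day", "occ_freq", "lay_day", "success"])
pdat = standardize_path_data(pdat[["site_id", "quality", "return_day",
                                   "occ_freq", "lay_day", "success"]]
                             .rename(columns={"lay_day": "lay_date"}))
posts = fit_all_pathways(pdat, config=MCMCConfig.fast(seed=1))
print(pathways_table(posts)[["pathway", "estimate", "pct_same_sign"]])
```

Or run everything from a shell:

```bash
colonywatch simulate --seed 1 --out out/
colonywatch metrics --scores out/image_scores.csv --filter any --out out/
colonywatch run --config examples/run.yaml
```

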