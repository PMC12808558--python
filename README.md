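# occupam

Dynamic (multi-season) occupancy modelling for passive acoustic
monitoring (PAM) programs, with fire-disturbance covariates and trend
estimation at multiple spatial scales.

`occupam` is written for wildlife monitoring programs that deploy
autonomous recording units (ARUs) across a sampling grid, classify the
audio with a neural-network call classifier, and need to turn the
resulting prediction tables into defensible inferences about occupancy
dynamics — initial occupancy, colonization, extinction, detection — and
population trend. The reference use case is landscape-scale monitoring
of a territorial owl across a fire-prone forest ecosystem, but every
stage is generic.

## What it does

1. **Detection processing** (`occupam.detections`): thresholds
   classifier confidence scores (default ≥ 0.989, inclusive), keeps the
   best call type per 3-s segment, removes predictions within 1.5 km of
   a same-night call-back survey, and aggregates nightly detections into
   a sites × years × 18-weeks encounter history. A cell-year is only
   coded as occupied when detections occur on ≥ 2 distinct nights,
   separating occupancy from transient site use. Weeks without recording
   effort are missing, not zero.
2. **Covariates** (`occupam.covariates`): latitude-residualized
   elevation, composite burn index (CBI ≥ 2.25) high-severity
   classification, cumulative proportion of each cell burned at high
   severity from 1985 to the season preceding each survey year, and
   standardized design matrices for all four submodels.
3. **The model** (`occupam.model`): a Bayesian dynamic occupancy model.
   Latent occupancy z[i,t] follows a two-state Markov chain,

       z[i,1] ~ Bernoulli(ψ_i),
       z[i,t+1] | z[i,t] ~ Bernoulli(z (1−ε_{i,t}) + (1−z) γ_{i,t}),
       y[i,t,j] | z[i,t] ~ Bernoulli(z[i,t] · p_{i,t,j}),

   with logit-linear submodels and forest-level random intercepts:
   ψ ~ canopy height, elevation + elevation², latitude + latitude²,
   burned proportion; γ and ε ~ burned proportion + year; p ~ log weekly
   recording hours, date + date², year. The latent states are
   marginalized by the forward algorithm; fitting is by posterior mode
   (`fit_map`) or MCMC (`sample_posterior`, an ensemble sampler over the
   marginalized posterior in a non-centered parametrization), with
   rank-normalized split-R̂ / bulk-ESS diagnostics and a
   MacKenzie–Bailey χ² posterior predictive check.
4. **Derived quantities** (`occupam.trends`): projected occupancy
   trajectories per draw, group summaries (region, forest, fire
   stratum), the mean annual rate of change λ̄ (arithmetic mean over
   intervals of ψ̄_{t+1}/ψ̄_t, per draw), probability of direction, the
   cumulative detection probability p* = 1 − (1−p)^n, and posterior CVs.
5. **Synthetic data** (`occupam.synth`): a first-class generator for
   landscapes, fire histories, latent dynamics, nightly detections and
   classifier-style prediction tables, so the whole pipeline is testable
   without field data. Defaults match the reference study conditions
   (ψ ≈ 0.3, γ ≈ 0.12, ε ≈ 0.39, weekly p ≈ 0.6, strong opposing fire
   effects on colonization and extinction).

A `click` CLI ties the stages into a reproducible pipeline
(`occupam simulate | build-history | fit | trends | gof`); every output
directory embeds its configuration and hash.

## Worked example

Simulate a 150-cell, 3-forest, 4-year survey, fit by MCMC, and
summarize trends by fire stratum:

```python
import numpy as np
from occupam import synth, model, trends, covariates as cov

years = [2021, 2022, 2023, 2024]
cells = synth.gen_landscape(n_cells=150, n_forests=3, seed=1)
burns = synth.gen_fire_history(cells, range(1985, 2025), seed=2)
params = synth.paper_like_params(3, forest_jitter=True,
                                 rng=np.random.default_rng(3))
truth = synth.simulate_occupancy(cells, burns, params, years, seed=4)
deps = synth.gen_deployments(cells, years, seed=5)
events, history = synth.simulate_detections(truth, deps, params, seed=6)
design = cov.build_design(cells, burns, history)

draws = model.sample_posterior(history, design, chains=1,
                               iter=1500, warmup=750, seed=7, thin=3)

flat = draws.subsample(300, seed=8)
psi = trends.project_occupancy(flat, design, template=draws.template)
groups = {"region": range(len(cells)), **trends.fire_strata(design)}
for g, s in trends.group_trajectory(psi, groups, years=years).items():
    print(g, s.psi_mean.round(2), round(s.lambda_bar_mean, 2),
          s.trend_direction, round(s.pd_trend, 2))
```

prints (formatted):

```
   region: psi 0.24 0.27 0.33 0.28  lambda-bar 1.07 (0.99-1.16)  PD(increase) 0.93
 unburned: psi 0.25 0.36 0.50 0.46  lambda-bar 1.25 (1.12-1.39)  PD(increase) 1.00
hs_lt_0.5: psi 0.25 0.28 0.34 0.29  lambda-bar 1.06 (0.97-1.14)  PD(increase) 0.91
hs_ge_0.5: psi 0.21 0.18 0.19 0.12  lambda-bar 0.85 (0.73-1.01)  PD(decline) 0.97
```

Cells burned mostly at high severity (`hs_ge_0.5`) decline (λ̄ = 0.85,
probability of decline 0.97) while unburned cells hold or gain — the
pattern the generating parameters encode. The posterior recovers the
fire effects with the right signs and magnitudes:

```
beta_gamma[prop_hs]: -0.82 (95% CrI -1.22 to -0.47)   # truth -0.77
beta_eps[prop_hs]:    0.60 (95% CrI  0.17 to  1.01)   # truth +0.73
beta_p[log_hours]:    0.59 (95% CrI  0.48 to  0.70)   # truth +0.58
```

λ̄ < 1 means mean occupancy across cells is shrinking; PD is the
posterior mass on the indicated side of λ̄ = 1 (or of zero, for
coefficients).

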