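# Methods

This note documents the statistical model, the processing rules, the
synthetic-data generator, and the numerical and design choices behind
`occupam`.

## The model

Sites are grid cells *i* = 1..N nested in forests *f(i)*; primary
occasions *t* are years; secondary occasions *j* are 18 week-long
windows anchored at April 1. The latent occupancy state z[i,t] ∈ {0,1}
starts as Bernoulli(ψ_i) and evolves as a two-state Markov chain with
colonization γ[i,t] (0→1) and extinction ε[i,t] (1→0). Conditional on
z[i,t] = 1, each surveyed week yields a detection with probability
p[i,t,j]; unoccupied site-years yield none (no false positives — the
processing pipeline is assumed to have removed them via manual
validation). All four probabilities are inverse-logit of linear
predictors in standardized covariates with forest-level random
intercepts α ~ Normal(μ, σ) per submodel (four independent intercept
vectors with independent SDs).

Covariates: initial occupancy uses canopy height, latitude-residualized
elevation (linear + quadratic), northing (linear + quadratic) and the
cumulative high-severity burned proportion; colonization/extinction use
the time-varying burned proportion plus transition-year fixed effects
(transitions labeled by start year, first year as reference);
detection uses log weekly recording hours, day-of-year of the week
midpoint (linear + quadratic) and year fixed effects. Canopy height
enters only initial occupancy (the canopy layer predates the first
survey year). Quadratic columns are squares of the standardized linear
columns and are not re-standardized, so coefficient pairs stay
interpretable.

The likelihood marginalizes z with the forward algorithm: per year the
z = 1 emission is the product of weekly Bernoulli terms over surveyed
weeks (missing weeks contribute a factor of 1), the z = 0 emission is
the indicator that no detection was recorded; transitions apply the
2×2 matrix [[1−γ, γ], [ε, 1−ε]]. The forward vector is renormalized
each year, so long histories cannot underflow. Probabilities are
clipped to [1e-12, 1−1e-12] and linear predictors to ±35 before
exponentiation. The recursion is verified against exhaustive
enumeration of all 2^T latent paths on thousands of random instances
(agreement to 1e-12).

## Priors and fitting

Defaults (all configurable via `PriorConfig`): coefficients
Normal(0, 2.5); forest intercepts Normal(μ, σ) with μ ~ Normal(0, 5)
and σ ~ half-Cauchy(0, 2.5), sampled on the log scale with the Jacobian
included. The full prior specification is recorded in the fit metadata.

`fit_map` maximizes the log posterior with multi-start L-BFGS-B
(default 5 starts) and reports observed-information standard errors.
The joint density of a hierarchical model is unbounded as σ → 0 with
α = μ, so log σ is boxed in [log 0.05, log 10]; a mode on the boundary
is flagged (`sigma_at_bound`). The mode is a fast surrogate — point
estimates and sign tests — not a replacement for the posterior.

`sample_posterior` runs an affine-invariant ensemble sampler (emcee)
over the marginalized posterior, using differential-evolution moves and
a **non-centered parametrization** of the intercepts
(α = μ + σ·α_raw, α_raw ~ Normal(0,1)) in the sampling space; draws are
transformed back for reporting. Both choices were adopted because the
centered stretch-move sampler failed to traverse the hierarchical
funnel (split-R̂ ≈ 1.6–2.6 at 300 cells regardless of chain length);
non-centered DE sampling reaches R̂ ≈ 1.1–1.3 with bulk ESS of several
hundred at 2,500 iterations. Walkers (default 2·dim + 2) start in a
small ball around the posterior mode; each walker trajectory is
recorded as a chain for the rank-normalized split-R̂ and bulk-ESS
diagnostics (pass: R̂ ≤ 1.01 and ESS > 300; failures are warned about
and recorded, never silently dropped). Because walkers interact within
an ensemble, walker-R̂ is an optimistic convergence signal; the `chains`
argument therefore runs fully independent ensembles (default 3). The
sampler is deterministic given `seed`. Correctness of the machinery is
cross-checked in the test suite against an independently written
random-walk Metropolis sampler on the same posterior.

## Goodness of fit

The MacKenzie–Bailey χ² posterior predictive check groups site-years by
year and surveyed-week pattern, computes the expected count of each
observed weekly history within a cohort (marginal occupancy ψ̃[i,t]
from the projected trajectory times the weekly Bernoulli product, plus
the never-detected mass for all-zero histories), pools expected mass
below 1e-6 together with the unobserved-history remainder, and compares
χ² on the data against χ² on one replicate per posterior draw
(Bayesian p = fraction of replicates at least as extreme). On data
simulated from the model itself the p-value lands in (0.05, 0.95) in
19 of 20 scaled-down replicate experiments; gross site heterogeneity in
p drives it below 0.05.

## Derived quantities

Trajectories are the *projected* (unconditional) variant:
ψ[i,1] from the initial submodel, then
ψ[i,t+1] = ψ[i,t](1−ε[i,t]) + (1−ψ[i,t])γ[i,t], per posterior draw,
not conditioned on the observed histories (a data-informed indicator
helper exists but is not used for trends). Group trajectories average
ψ over the group's cells per draw; built-in groupers are all-cells,
forest, and fire stratum (unburned / < 0.5 / ≥ 0.5 cumulative
high-severity proportion, membership evaluated at a reference year,
default the final year, because the proportion is time-varying).
λ̄_t = ψ̄_{t+1}/ψ̄_t and λ̄ is the **arithmetic** mean of the T−1
ratios, per draw — exactly the displayed estimator, not a geometric
mean, despite the "annual growth rate" phrasing. The probability of
direction is the posterior mass on the dominant side of the reference
(1 for trends, 0 for coefficients), with ties split evenly. The
cumulative detection probability is p* = 1 − (1−p)^n; at the published
weekly p = 0.57 and a five-week deployment, p* = 0.985.

## Detection processing rules

- Confidence threshold 0.989, **inclusive**.
- Best call per (recorder, night, 3-s segment); ties broken by a fixed
  call-type precedence (four-note > contact > crow bark > monkey hoot >
  juvenile begging) for determinism — ties are measure-zero in real
  scores.
- Call-back exclusion: planar Euclidean distance in the projected CRS,
  boundary inclusive at exactly 1.5 km, same survey night only.
- A "night" is labeled by the date at 20:00 (the 20:00–06:00 analysis
  window spans midnight under one label); nightly hours are capped at
  10 accordingly.
- Week index = floor((night − April 1)/7) + 1; nights outside weeks
  1–18 are dropped with a logged count. A fixed calendar anchor keeps
  histories comparable across years.
- The ≥ 2-nights occupancy qualification pools all recorders and all
  weeks within the cell-year; the two nights need not fall in different
  weeks (the minimal-assumption reading).
- Weeks partially censored by mid-week deployment starts/stops keep
  their partial effort hours; the log-hours detection covariate absorbs
  the difference rather than the week being discarded.
- Filtering is idempotent; an event in a cell-week with zero recorded
  effort is a hard error (inconsistent inputs, not missing data).

## The synthetic-data generator

The generator emulates the study frame the model assumes, and its
defaults are the study conditions: baseline ψ ≈ 0.3, γ ≈ 0.12,
ε ≈ 0.39, weekly p ≈ 0.6; coefficient preset from the published point
estimates (canopy +1.14; elevation −0.24/−0.43; latitude −0.89/−0.21;
burned proportion −0.19 on ψ, −0.77 on γ, +0.73 on ε; log-hours +0.58;
date +0.01/−0.17; final-year detection −0.17). Random-intercept SDs are
not published; σ = 0.5 on all four submodels is used as moderate
forest-level heterogeneity. Landscapes place forests as contiguous
blocks along northing with an elevation gradient plus noise; fires are
Poisson(5.5/yr) over contiguous cell blocks whose sizes are lognormal
fractions of the landscape (median 0.25%, heavy tail for megafires),
with per-cell newly-burned high-severity fractions Beta(1.5, 5) (mean
0.23). Over the 1985–2024 record this yields ≈ 40% of cells never
burned, ≈ 50% below 0.5 cumulative high severity and ≈ 10% at or above
it — the stratification the trend groupers target. Deployments run two
recorders per cell for ~34 nights (SD 7) starting in weeks 1–8, 10 h
per night.

The weekly detection probability from the submodel is spread uniformly
over the week's m surveyed nights as q = 1 − (1−p)^{1/m}, so that the
probability of ≥ 1 detection night equals p exactly; nights are assumed
conditionally independent within a week (night-to-night correlation is
not modeled — the weekly model is agnostic to it, but the ≥ 2-nights
rule operates on nights, so an allocation was needed). The simulator's
truth history codes a week 1 on ≥ 1 detection night (the model's weekly
outcome); the ≥ 2-nights rule belongs to the history builder, and the
two agree exactly when detection is saturating — the round-trip test.
ψ, γ, ε are computed by the same design-building and link code used in
fitting, so simulation and estimation cannot drift apart.

What the generator does *not* emulate: realistic fire spread geometry
(footprints are 1-D contiguous blocks — only the covariate distribution
matters to the model), spatial autocorrelation between neighboring
cells, classifier confidence calibration, barred-owl interference, or
observer behavior in call-back surveys. Passing tests therefore
demonstrate correctness of the estimator under the model's own
assumptions, and calibration at realistic sample sizes and rates — not
robustness to the spatial or acoustic structure of real field data.

## Fire covariate accumulation

High severity is CBI ≥ 2.25 (inclusive), CBI clamped to [0, 3] with a
warning. Cumulative burned proportion for season *t* accumulates fires
from 1985 through *t* − 1 (the monitoring year's own fires are
excluded); transitions labeled by start year *s* carry the proportion
through *s* − 1, matching the convention that a colonization/extinction
covariate for transition *s* → *s*+1 is the value attached to year *s*.
With per-pixel masks the proportion is the exact pixel union; with
scalar per-fire fractions the union is approximated by
1 − Π(1 − fraction) — exact under independent placement, an
overestimate for nested fires, an underestimate for disjoint ones; the
scalar path exists for synthetic and tabular inputs. The proportion is
non-decreasing in monitoring year by construction.

## Problem sizes used in the automated checks

Likelihood oracle: 1,000 random instances, T ≤ 4, J ≤ 5. Parameter
recovery: 20 replicate datasets of 300 cells × 4 years × 18 weeks
(posterior-mode sign recovery of both fire effects), plus one full MCMC
fit at the same scale (2,500 iterations, 1,250 warm-up) for interval
coverage of the 18 fixed-effect coefficients. Goodness-of-fit
calibration: 20 replicates of 80 cells × 3 years × 6 weeks with an
intercept-only two-forest model. These sizes keep the complete suite
under ten minutes on one CPU while staying in the regime where the
published effects are identifiable.

## Known limitations

- Walker-based R̂ within one ensemble is optimistic; use `chains ≥ 2`
  (independent ensembles) when convergence certification matters.
- `fit_map` reports a penalized mode of a hierarchical posterior;
  σ estimates at the box boundary indicate the mode is not interior and
  the MCMC path should be used.
- λ̄ for very small groups (single cells) is noisy and can explode when
  group mean occupancy approaches zero; ratios are only meaningful for
  groups whose ψ̄ is bounded away from 0.
- The false-positive process is handled entirely by the validation
  flags in the prediction table; no misclassification model is fitted.
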