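# Methods

This note documents the models, algorithms, and numerical choices behind
`whaleresp`, and what the synthetic-data tests do and do not demonstrate
about real field data.

## Scientific setting

Pacific Coast Feeding Group (PCFG) gray whales forage in very shallow
(<20 m) coastal habitat, where buoyancy works against a diving whale for the
whole dive.  Because respiration is the accessible proxy for oxygen
consumption in free-ranging whales, the package quantifies breath-by-breath
surface behavior and links it to morphology (total length TL, m; body-area
index BAI, a standardized body-condition score) and dive behavior, then
propagates the fitted relationships into a daily field-metabolic-rate (FMR)
simulation.

## Respiration metrics

A *surface sequence* runs from the first breath after a dive to the final
breath before the next dive.  Each breath is annotated as a (start, end)
blow interval; inhalation duration is one-half of the blow duration
(inhalation and exhalation durations are equal in gray whales).  Per
sequence we compute: breath count; sequence duration (start of initial
breath to start of terminal breath — symmetric endpoints, a deliberate
choice since only "between the initial and terminal breaths" is defined);
total inhalation duration (sum of per-breath inhalations); mean inter-breath
interval (IBI), defined as the *end-to-start gap* so that dive time, gaps,
and inhalation time are disjoint components of a dive-recovery cycle; and
the inhalation accumulation rate, the OLS slope (free intercept, current
breath included in the cumulative sum) of cumulative inhalation duration
against time since the first breath.  Metrics undefined for single-breath
sequences (IBI, slope, terminal duration) are emitted as missing, never 0.

Nares area is standardized by TL (area/TL by default; the divisor exponent
is configurable because area/TL² is equally defensible).  BAI estimates are
matched to an observation date same-day first, otherwise nearest within ±14
days, ties resolved to the earlier date.

## Tag processing

Dives are maximal runs of samples with depth ≥ threshold; a run of k samples
at rate fs represents k/fs seconds, and runs shorter than `min_duration`
(default 5 s for whale-scale dives) are discarded.  Breaths within a surface
period are surfacings (runs < 0.2 m) bounded by very shallow dips; any
surfacing longer than 10 s counts exactly two breaths (the validated
minimum), and such surfacings are flagged because the true count could be
higher.  Counts are minimum estimates.  No smoothing is applied by default;
a moving-median filter is available for noisy records.

For synthetic round trips, main dives are detected at a 1 m threshold
rather than 0.2 m: the generator's between-breath dips (0.5 m) last longer
than `min_duration`, so a 0.2 m dive pass alone cannot distinguish dives
from within-sequence dips.  Field workflows identify main dives manually;
the threshold is an explicit parameter here.

## Synthetic-data generator

The generator is first-class, tested code that defines the study conditions
for every downstream check.  Sequence-level responses follow log-linear
mixed models with per-whale random intercepts; the default coefficients are
the published recovery-model posterior means (intercepts 0.83 / 1.01 / 2.64
for breath count, total inhalation, IBI), so the synthetic population
breathes like the field population.  Breath counts are zero-truncated
Poisson (a surfacing implies at least one breath).  TL ~ Normal(10.5, 1.5²)
m truncated positive; BAI ~ Normal(27, 3.5²); measurement noise (default
0.2 m TL, 1.0 BAI) is added to produce the reported posterior means, and
the reported sd is the measurement sd.  Dive durations are lognormal
(log-mean 4.6 ≈ 100 s, log-sd 0.4); tactics are categorical over the five
field tactic groups; bubble blasts are Bernoulli(0.2).

Within-sequence structure is not constrained by the sequence-level models,
so it is parameterized: total inhalation splits across breaths, and gaps
scatter around the mean IBI, with lognormal proportions (log-sds 0.2 / 0.3).
Two calibrations tie the generator to reported field statistics:

- the total-inhalation residual log-sd (0.50) makes the generating model
  explain about as much variance as the fitted field model reports
  (Bayes R² ≈ 0.26);
- a Gaussian copula (ρ = 0.99) couples each sequence's count and
  total-inhalation draws, reproducing the strong observed correlation
  between the two metrics (r ≈ 0.92 synthetic vs 0.96 observed) while
  leaving both marginals exactly as modeled.  Without the copula the
  correlation ceiling is ≈0.8, because a discrete count cannot correlate
  more tightly with a continuous total.

Depth series are built per whale from the chained timeline dive₀,
sequence₀, dive₁, …: trapezoidal dive profiles (descent rate 1 m/s to the
dive's maximum depth), 0.5 m between-breath dips, 0.05 m during breaths.
The sample nearest each breath midpoint and each gap midpoint is forced to
the corresponding depth, so events survive sampling provided durations and
gaps exceed two sample periods (defaults: 1 Hz, IBIs ≈ 14 s).

What the generator does *not* emulate: sensor noise structure of real
pressure records, depth-dependent dive shapes, HMM-derived behavior
uncertainty, temporal autocorrelation between sequences, or missing-data
patterns of drone focal follows.  Passing round-trip tests therefore show
algorithmic correctness under clean conditions, not field robustness.

## Bayesian mixed models

Table of designs: recovery / anticipation / combined foraging models and a
travel model, over responses breath count (Poisson log link), total
inhalation duration, mean IBI, accumulation rate, initial/terminal breath
duration, travel respiration rate (all Gaussian on the natural log).
Recovery designs take dive covariates from the preceding dive, anticipation
from the following dive; the combined design keeps only tactic-matched
sequences, includes both dive durations, and drops the bubble covariate.
Breath-count likelihoods are zero-truncated by default, matching how the
data arise (plain Poisson available via a flag).

Continuous covariates are z-scored (sample sd, n−1); constants are stored
with the fit and required for prediction.  Measurement error in TL and BAI
is handled by imputation: each unit's true value is a latent parameter with
an independent Normal(reported mean, reported sd) prior, entering the
linear predictor through the stored z-scoring constants.  Latents are keyed
per whale (the synthetic data carry one TL and one BAI posterior per
whale); with dated BAI series the same machinery applies per unit row.

Priors (the originals are unpublished; these are weakly informative
defaults, configurable): Normal(0,1) for slopes and tactic contrasts,
Normal(data center, 2) for the intercept, Exponential(1) for the random-
intercept and residual sds.  Reference levels: headstand tactic, no bubble
blast.

### Sampler

Inference is by a purpose-built Gibbs / Metropolis-within-Gibbs engine:

- Gaussian family: conjugate block updates for the fixed effects, random
  intercepts, and latent covariates (the model is linear in each latent);
  slice sampling for the two sds.
- Poisson family: adaptive random-walk Metropolis for the fixed-effect
  block (proposal covariance learned during warmup, Robbins–Monro scale
  targeting 0.234 acceptance), vectorized per-unit Metropolis for random
  intercepts and latents (conditionally independent across units), slice
  sampling for the random-intercept sd.

Both families interweave the centered sd update with a non-centered one
(u = σ_u·ũ): the centered conditional mixes arbitrarily slowly as σ_u → 0,
and the interweaving restores effective sample sizes from tens to
thousands.  Chains are seeded from (seed, chain) via SeedSequence, so fits
are bit-reproducible.  The convergence contract — R-hat < 1.01 and ESS >
400 (arviz) on all reported parameters — is enforced by default and raises
a diagnostics error otherwise.

Default test-scale settings are 3 chains × 13,000 iterations (2,500
warmup) for Poisson and 3 × 4,500 (1,000) for Gaussian, which meet the
contract at the problem sizes used throughout (≈200–500 sequences, 10–50
whales) in seconds per fit; the field-scale settings (3 × 90,000 with
30,000 warmup; travel 3 × 30,000 with 10,000) are available through
`MCMCSettings.production_foraging()` / `production_travel()`.

### Summaries

Coefficients are reported as posterior mean, central 95% credible interval,
and the percent of the posterior on the majority side of zero (∈ [50,100],
matching the reporting convention).  Bayes R² is computed per draw as
var(fitted)/(var(fitted)+var(residual)) on the link/log scale, with
residual variance σ² for the Gaussian family and the delta-method
approximation mean(1/λ) for the Poisson family.  The Poisson dispersion
statistic is the posterior mean of Σ Pearson residuals² / (n−p).  Residual
autocorrelation uses posterior-mean residuals (Pearson residuals for
Poisson) with ±1.96/√n white-noise bands; constant residual series are
flagged as degenerate rather than reported.

## FMR simulation

Each simulated day divides into a foraging budget (36% of 86,400 s) and a
combined travel/search budget (43% + 21%); travel and search are pooled
because their stroke rates are indistinguishable.  Foraging fills the
budget with complete dive-recovery cycles: dive duration + (zero-truncated
Poisson breath count) IBI draws + one total-inhalation draw, with the
Poisson mean and the lognormal parameters predicted from the recovery
models at the grid combination.  The cycle that first reaches the budget is
included in full (overshoot < one cycle, bias < 0.5%).  Travel fills its
budget with alternating lognormal breath holds (log-mean 3.66, log-sd 0.65;
mean ≈ 48 s) and inhalations (0.26, 0.17; mean ≈ 1.32 s) estimated from the
field travel data.

Summed daily inhalation time converts to tidal volume,
V_T(daily) = −7.24 + 2.14·t_in(daily)·TL², and then to FMR = H·%O₂·V_T with
one oxygen-extraction draw per day from Normal(0.11, 0.027) truncated to
(0,1).  H defaults to 0.002 MJ per liter O₂ as published for this pipeline;
note the conventional oxygen caloric equivalent is ≈0.0201 MJ L⁻¹, so
absolute FMR magnitudes depend strongly on this configurable choice, while
every Cohen's-d comparison is exactly invariant to it.  Prey requirements
divide FMR by the composite prey energy density (1.91 kJ g⁻¹, converted to
metric tons).

The covariate grid is TL {9, 12} m × BAI {22, 27, 32} × dive duration
{60, 120, 300} s × tactic {headstand, forward swimming} (36 combinations;
20,000 iterations each at production scale, 5,000 in the acceptance
recomputation — Monte Carlo error on the family-mean d values is well
below the stochastic comparison tolerance at either size).  Effects are
summarized as Cohen's d, (m₁−m₂)/√((s₁²+s₂²)/2), across all matched pairs
of a comparison family (18 pairs for TL and tactic, 12 for each BAI and
dive contrast).  Each combination uses an independent RNG substream
spawned from the root seed in fixed grid order, so matched comparisons are
stable across configurations.

Plug-in details the published tables do not determine: the z-scoring
constants of the original fits are unprinted, so defaults spanning the
grid are used (TL 10.5 ± 1.5 m, BAI 27 ± 5, dive 120 ± 120 s; all
configurable and logged); per-cycle IBI and total-inhalation draws use a
configurable lognormal log-sd defaulting to 0 (point predictions), since
day-level FMR variance is dominated by the oxygen-extraction draw and the
effect sizes are insensitive to this spread.  The O₂ fraction is drawn once
per simulated day.  Random-intercept variance is excluded from plug-in
predictions by construction (the intercept is set to zero).

Known behaviors worth flagging: direct per-iteration prey conversion is
used, which can differ in the second decimal from published prey values
that may have been converted after summarizing; and simulated whales dive a
single fixed duration all day, so short-dive days include many more
recoveries — the source of the negative dive-duration effect on daily FMR.

## Limitations

- The field dataset is not bundled; fitted coefficients here come from
  synthetic data, and the published posterior means are used only as
  plug-in inputs to the FMR grid.
- The sampler is designed for the moderate dimensions of these designs
  (tens of whales, hundreds of sequences), not for arbitrary GLMMs.
- Travel models and tag breath counts share the drone-calibrated 10-s rule;
  surfacings much longer than 10 s still count only two breaths, so travel
  respiration rates are conservative.
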