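# whaleresp

Respiration energetics of baleen whales foraging in shallow habitat.

Pacific Coast Feeding Group (PCFG) gray whales feed in water shallower than
20 m, where buoyancy raises the cost of every dive.  Because oxygen
consumption cannot be measured directly in free-ranging whales, respiration
at the surface is the accessible proxy: how many breaths a whale takes, how
long it inhales, and how quickly it accumulates inhalation time after a
dive.  `whaleresp` implements that analysis chain end to end:

- **Respiration metrics** from drone-annotated breath events: inhalation
  duration (half the blow duration), total inhalation duration, mean
  inter-breath interval (IBI), inhalation accumulation rate (the OLS slope
  of cumulative inhalation time vs. time since the first breath), breath
  classes, travel respiration rate, swim speed, TL-standardized nares area,
  ±14-day BAI date matching.
- **Tag processing**: dive detection from depth series by threshold
  crossing, minimum breath counts from surfacings between very shallow
  dives (a surfacing longer than 10 s counts as two breaths), travel-series
  grouping.
- **Bayesian mixed models** (`y ~ TL + BAI + dive duration + bubble blast +
  tactic + (1 | whale)`): Poisson log-link for breath counts
  (zero-truncated), Gaussian on the log scale for continuous metrics, with
  photogrammetric uncertainty in TL and BAI imputed as latent covariates
  (Normal priors at each whale's reported mean/sd).  Recovery designs
  attach covariates from the dive *preceding* a surface sequence,
  anticipation designs from the dive *following* it.  Fitting is by a
  built-in Gibbs / adaptive-Metropolis engine with an enforced convergence
  contract (R-hat < 1.01, ESS > 400).
- **Daily FMR Monte Carlo**: fills each simulated day's foraging budget
  with dive-recovery cycles and its travel/search budget with breath-hold
  cycles, converts summed inhalation time to tidal volume
  (V_T = −7.24 + 2.14·t_in·TL²) and FMR (H·%O₂·V_T), derives prey
  requirements, and compares covariate levels with Cohen's d across a
  36-combination grid.
- **Synthetic data**: a generator with known ground truth (log-linear mixed
  models, measurement error, tag-style depth series) that makes the whole
  pipeline testable without any field data.

Intended users: marine-mammal ecologists and biologging analysts who want a
tested, scriptable version of this workflow, or a simulation bench for
respiration-based energetics methods.

## Worked example

```sh
python examples/04_fmr_simulation.py
```

```
extreme combinations:
 tl  bai  dive_duration           tactic  fmr_mean_mj  prey_mean_t
9.0 22.0          300.0 forward_swimming       65.498        0.034
  tl  bai  dive_duration    tactic  fmr_mean_mj  prey_mean_t
12.0 32.0           60.0 headstand      156.804        0.082

effect sizes across matched pairs (Cohen's d, mean +/- sd):
  TL 12-9                       2.24 +/- 0.06  (18 pairs)
  BAI 27-22                     0.08 +/- 0.04  (12 pairs)
  BAI 32-22                     0.17 +/- 0.05  (12 pairs)
  BAI 32-27                     0.08 +/- 0.05  (12 pairs)
  Dive 120-300                  0.44 +/- 0.05  (12 pairs)
  Dive 60-120                   0.46 +/- 0.08  (12 pairs)
  Dive 60-300                   0.90 +/- 0.10  (12 pairs)
  Tactic headstand-forward      0.12 +/- 0.07  (18 pairs)
```

The cheapest day belongs to a small, lean whale doing long forward-swimming
dives; the most expensive to a large, high-condition whale doing short
headstands.  Body length dominates the effect-size ranking (d > 2, because
tidal volume scales with TL²), dive duration is moderate, and tactic choice
is nearly negligible (d ≈ 0.1).  Cohen's d values are invariant to the heat
coefficient H, which only scales absolute FMR (MJ/day).

The other examples show the metric computations (`01`), tag-style breath
detection recovering generating counts exactly on noiseless depth series
(`02`), and a full mixed-model fit with measurement-error imputation and
Bayes R² (`03`).  A thin CLI wraps the same stages:

```sh
whaleresp simulate-data --n-whales 10 --n-sequences 6 --seed 1 --out sim/
whaleresp compute-metrics --events sim/breath_events.csv --dives sim/dives.csv --out metrics.csv
whaleresp simulate-fmr --iterations 5000 --seed 1 --out fmr/
whaleresp run-pipeline --seed 1 --out run/
```

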