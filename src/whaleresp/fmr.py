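"""Monte Carlo simulation of daily field metabolic rate (FMR).

A simulated day splits into a foraging period and a combined travel/search
period according to a fixed activity budget.  During foraging, complete
dive-recovery cycles (dive + breath-count-many inter-breath intervals + one
total-inhalation draw) are generated until the period is filled; during
travel/search, alternating breath-hold and single-inhalation draws fill the
period.  The summed daily inhalation time t_in(daily) converts to a daily
tidal volume

    V_T(daily) = -7.24 + 2.14 * t_in(daily) * TL^2       [liters]

and, with an oxygen-extraction fraction drawn once per day and a heat
conversion H (MJ per liter O2),

    FMR_daily = H * %O2 * V_T(daily)                     [MJ/day].

Prey requirements divide FMR by the caloric density of the composite local
prey.  FMR is simulated over the full covariate grid (TL x BAI x dive
duration x foraging tactic) with respiration predictions from the recovery
models, and covariate effects are summarized as Cohen's d across matched
combination pairs — these standardized effects are invariant to the choice
of H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .models import PredictedResponse, predict_response
from .coefficients import RECOVERY_POSTERIOR_MEANS, default_standardization

__all__ = [
    "FMRConfig",
    "FMRResult",
    "ForagingPeriodResult",
    "TravelPeriodResult",
    "COMPARISON_FAMILIES",
    "tidal_volume_daily",
    "fmr_daily",
    "prey_requirement",
    "cohens_d",
    "simulate_foraging_period",
    "simulate_travel_period",
    "simulate_day",
    "grid_predictions",
    "run_grid",
]

SECONDS_PER_DAY = 86_400.0

# (label, axis, level_a, level_b): d compares a minus b across matched pairs
COMPARISON_FAMILIES = (
    ("TL 12-9", "tl", 12.0, 9.0),
    ("BAI 27-22", "bai", 27.0, 22.0),
    ("BAI 32-22", "bai", 32.0, 22.0),
    ("BAI 32-27", "bai", 32.0, 27.0),
    ("Dive 120-300", "dive_duration", 120.0, 300.0),
    ("Dive 60-120", "dive_duration", 60.0, 120.0),
    ("Dive 60-300", "dive_duration", 60.0, 300.0),
    ("Tactic headstand-forward", "tactic", "headstand", "forward_swimming"),
)


@dataclass
class FMRConfig:
    """Constants and covariate grid for the daily FMR simulation."""

    h_mj_per_l_o2: float = 0.002
    o2_extraction_mean: float = 0.11
    o2_extraction_sd: float = 0.027
    activity_budget: dict = field(default_factory=lambda: {
        "forage": 0.36, "search": 0.43, "travel": 0.21})
    travel_hold_log_mean: float = 3.66
    travel_hold_log_sd: float = 0.65
    travel_inhalation_log_mean: float = 0.26
    travel_inhalation_log_sd: float = 0.17
    prey_energy_kj_per_g: float = 1.91
    tl_values_m: tuple = (9.0, 12.0)
    bai_values: tuple = (22.0, 27.0, 32.0)
    dive_durations_s: tuple = (60.0, 120.0, 300.0)
    tactics: tuple = ("headstand", "forward_swimming")
    iterations: int = 20_000
    plugin_log_sd: float = 0.0   # per-cycle lognormal spread in plug-in mode
    seed: int = 0

    def __post_init__(self):
        total = sum(self.activity_budget.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"activity budget sums to {total}, expected 1")
        for k, v in self.activity_budget.items():
            if not 0 < v < 1:
                raise ValidationError(f"budget fraction {k!r} not in (0,1)")
        for name in ("o2_extraction_sd", "travel_hold_log_sd",
                     "travel_inhalation_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.plugin_log_sd < 0:
            raise ValidationError("plugin_log_sd must be non-negative")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")

    @property
    def foraging_budget_s(self) -> float:
        return SECONDS_PER_DAY * self.activity_budget["forage"]

    @property
    def travel_budget_s(self) -> float:
        return SECONDS_PER_DAY * (self.activity_budget["search"]
                                  + self.activity_budget["travel"])

    def combos(self):
        return [
            {"tl": tl, "bai": bai, "dive_duration": dive, "tactic": tac}
            for tl, bai, dive, tac in product(
                self.tl_values_m, self.bai_values, self.dive_durations_s,
                self.tactics)]


@dataclass
class ForagingPeriodResult:
    t_in_s: float
    duration_s: float
    n_cycles: int


@dataclass
class TravelPeriodResult:
    t_in_s: float
    duration_s: float
    n_cycles: int


def tidal_volume_daily(t_in_daily_s: float, tl_m: float) -> float:
    """Daily tidal volume (L) from summed inhalation time and body length.

    The intercept makes very small inhalation sums nonphysical (negative
    volume); realistic daily sums are far above that regime.
    """
    if tl_m <= 0:
        raise ValidationError("total length must be positive")
    if t_in_daily_s < 0:
        raise ValidationError("inhalation time must be non-negative")
    return -7.24 + 2.14 * t_in_daily_s * tl_m ** 2


def fmr_daily(h_mj_per_l: float, o2_fraction: float,
              vt_daily_l: float) -> float:
    """Daily field metabolic rate (MJ): H * %O2 * V_T(daily)."""
    if not 0.0 <= o2_fraction <= 1.0:
        raise ValidationError("O2 extraction fraction must lie in [0, 1]")
    if h_mj_per_l < 0 or vt_daily_l < 0:
        raise ValidationError("H and tidal volume must be non-negative")
    return h_mj_per_l * o2_fraction * vt_daily_l


def prey_requirement(fmr_mj: float, energy_density_kj_per_g: float = 1.91):
    """Metric tons of prey per day to meet an FMR (MJ/day)."""
    if energy_density_kj_per_g <= 0:
        raise ValidationError("prey energy density must be positive")
    if np.any(np.asarray(fmr_mj) < 0):
        raise ValidationError("FMR must be non-negative")
    grams = np.asarray(fmr_mj) * 1000.0 / energy_density_kj_per_g
    tons = grams / 1e6
    return float(tons) if np.isscalar(fmr_mj) else tons


def cohens_d(draws_a, draws_b) -> float:
    """Standardized mean difference with pooled sd sqrt((s1^2+s2^2)/2)."""
    a = np.asarray(draws_a, float)
    b = np.asarray(draws_b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 draws per group")
    pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        raise ValidationError("zero pooled sd")
    return float((a.mean() - b.mean()) / pooled)


def _lognormal(rng, mu, sigma, size=None):
    if sigma == 0:
        return (np.full(size, math.exp(mu)) if size is not None
                else math.exp(mu))
    return np.exp(rng.normal(mu, sigma, size))


def _draw_count(rng, lam, fixed_count=None):
    if fixed_count is not None:
        return int(fixed_count)
    if lam <= 0:
        raise ValidationError("Poisson mean must be positive")
    c = rng.poisson(lam)
    while c == 0:
        c = rng.poisson(lam)
    return int(c)


def simulate_foraging_period(count_mean: float, ibi: tuple, t_in: tuple,
                             dive_duration_s: float, budget_s: float,
                             rng: np.random.Generator,
                             fixed_count: int | None = None
                             ) -> ForagingPeriodResult:
    """Fill a foraging period with complete dive-recovery cycles.

    Each cycle is ``dive_duration + (breath count) IBI draws + one
    total-inhalation draw``; the breath count is zero-truncated
    Poisson(``count_mean``) (or ``fixed_count``), and ``ibi`` / ``t_in`` are
    (log-mean, log-sd) lognormal parameters.  Cycles accumulate until the
    elapsed time first reaches or exceeds the budget; the crossing cycle is
    included in full.
    """
    if budget_s < 0:
        raise ValidationError("budget must be non-negative")
    if fixed_count is None and count_mean <= 0:
        raise ValidationError("Poisson mean must be positive")
    ibi_mu, ibi_sd = ibi
    tin_mu, tin_sd = t_in
    t = 0.0
    tin_total = 0.0
    cycles = 0
    while t < budget_s:
        count = _draw_count(rng, count_mean, fixed_count)
        ibi_sum = float(np.sum(_lognormal(rng, ibi_mu, ibi_sd, count)))
        tin = float(_lognormal(rng, tin_mu, tin_sd))
        t += dive_duration_s + ibi_sum + tin
        tin_total += tin
        cycles += 1
    return ForagingPeriodResult(t_in_s=tin_total, duration_s=t,
                                n_cycles=cycles)


def simulate_travel_period(hold: tuple, inhalation: tuple, budget_s: float,
                           rng: np.random.Generator) -> TravelPeriodResult:
    """Fill a travel/search period with alternating hold + inhalation draws."""
    if budget_s < 0:
        raise ValidationError("budget must be non-negative")
    hold_mu, hold_sd = hold
    inh_mu, inh_sd = inhalation
    t = 0.0
    tin_total = 0.0
    cycles = 0
    while t < budget_s:
        h = float(_lognormal(rng, hold_mu, hold_sd))
        i = float(_lognormal(rng, inh_mu, inh_sd))
        t += h + i
        tin_total += i
        cycles += 1
    return TravelPeriodResult(t_in_s=tin_total, duration_s=t,
                              n_cycles=cycles)


def _draw_o2(rng, mean, sd, size=None):
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_day(combo: dict, predictions: dict, config: FMRConfig,
                 rng: np.random.Generator) -> tuple[float, float]:
    """One Monte Carlo day at one covariate combination: (FMR MJ, prey t).

    ``predictions`` maps ``breath_count`` (Poisson mean), ``mean_ibi`` and
    ``total_inhalation`` (lognormal parameters) to
    :class:`PredictedResponse` objects at this combo.
    """
    missing = {"breath_count", "mean_ibi", "total_inhalation"} - set(predictions)
    if missing:
        raise ValidationError(f"missing predictions: {sorted(missing)}")
    pc = predictions["breath_count"]
    pi = predictions["mean_ibi"]
    pt = predictions["total_inhalation"]
    forage = simulate_foraging_period(
        count_mean=math.exp(pc.mu), ibi=(pi.mu, pi.sigma),
        t_in=(pt.mu, pt.sigma), dive_duration_s=combo["dive_duration"],
        budget_s=config.foraging_budget_s, rng=rng)
    travel = simulate_travel_period(
        hold=(config.travel_hold_log_mean, config.travel_hold_log_sd),
        inhalation=(config.travel_inhalation_log_mean,
                    config.travel_inhalation_log_sd),
        budget_s=config.travel_budget_s, rng=rng)
    t_in_daily = forage.t_in_s + travel.t_in_s
    o2 = float(_draw_o2(rng, config.o2_extraction_mean,
                        config.o2_extraction_sd))
    vt = tidal_volume_daily(t_in_daily, combo["tl"])
    fmr = fmr_daily(config.h_mj_per_l_o2, o2, vt)
    return fmr, prey_requirement(fmr, config.prey_energy_kj_per_g)


def grid_predictions(config: FMRConfig, coefficients=None, constants=None,
                     log_sd: float | None = None) -> dict:
    """Plug-in respiration predictions for every grid combination.

    ``coefficients`` defaults to the published recovery-model posterior
    means; ``constants`` to the default z-scoring constants.  Returns
    ``{combo_index: {response: PredictedResponse}}`` in grid order.
    """
    coefficients = coefficients or RECOVERY_POSTERIOR_MEANS
    constants = constants or default_standardization()
    log_sd = config.plugin_log_sd if log_sd is None else log_sd
    out = {}
    for i, combo in enumerate(config.combos()):
        out[i] = {
            "breath_count": predict_response(
                coefficients["breath_count"], combo, constants,
                family="poisson"),
            "mean_ibi": predict_response(
                coefficients["mean_ibi"], combo, constants,
                family="lognormal", sigma=log_sd),
            "total_inhalation": predict_response(
                coefficients["total_inhalation"], combo, constants,
                family="lognormal", sigma=log_sd),
        }
    return out


# ---------------------------------------------------------------- vectorized

def _ztpois_vec(rng, lam, n):
    out = rng.poisson(lam, n)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(lam, int(bad.sum()))
        bad = out == 0
    return out


def _lognormal_vec(rng, mu, sd, shape):
    if sd == 0:
        return np.full(shape, math.exp(mu))
    return np.exp(rng.normal(mu, sd, shape))


def _foraging_tin_vec(lam, ibi, tin_p, dive, budget, rng, n):
    ibi_mu, ibi_sd = ibi
    tin_mu, tin_sd = tin_p
    t = np.zeros(n)
    tin = np.zeros(n)
    active = np.arange(n)
    while active.size:
        m = active.size
        counts = _ztpois_vec(rng, lam, m)
        kmax = int(counts.max())
        draws = _lognormal_vec(rng, ibi_mu, ibi_sd, (m, kmax))
        mask = np.arange(kmax)[None, :] < counts[:, None]
        ibi_sum = (draws * mask).sum(axis=1)
        tin_draw = _lognormal_vec(rng, tin_mu, tin_sd, m)
        t[active] += dive + ibi_sum + tin_draw
        tin[active] += tin_draw
        active = active[t[active] < budget]
    return tin


def _travel_tin_vec(hold, inh, budget, rng, n, chunk=2000):
    hold_mu, hold_sd = hold
    inh_mu, inh_sd = inh
    mean_cycle = (math.exp(hold_mu + hold_sd ** 2 / 2)
                  + math.exp(inh_mu + inh_sd ** 2 / 2))
    m = int(budget / mean_cycle * 1.4) + 30
    out = np.empty(n)
    for lo in range(0, n, chunk):
        rows = min(chunk, n - lo)
        holds = _lognormal_vec(rng, hold_mu, hold_sd, (rows, m))
        inhs = _lognormal_vec(rng, inh_mu, inh_sd, (rows, m))
        cum = np.cumsum(holds + inhs, axis=1)
        while (cum[:, -1] < budget).any():    # rare: append more cycles
            extra = m // 2 + 10
            holds = np.hstack([holds, _lognormal_vec(
                rng, hold_mu, hold_sd, (rows, extra))])
            inhs = np.hstack([inhs, _lognormal_vec(
                rng, inh_mu, inh_sd, (rows, extra))])
            cum = np.cumsum(holds + inhs, axis=1)
        idx = np.argmax(cum >= budget, axis=1)
        inh_cum = np.cumsum(inhs, axis=1)
        out[lo:lo + rows] = inh_cum[np.arange(rows), idx]
    return out


@dataclass
class FMRResult:
    """Per-combination FMR/prey summaries and matched-pair effect sizes."""

    config: FMRConfig
    combos: pd.DataFrame          # one row per covariate combination
    fmr_draws: dict               # combo index -> draws (MJ/day)
    prey_draws: dict              # combo index -> draws (t/day)
    pairwise: pd.DataFrame        # one row per matched pair
    comparisons: pd.DataFrame     # one row per comparison family

    def family_d(self, label: str) -> tuple[float, float]:
        row = self.comparisons.set_index("family").loc[label]
        return float(row["d_mean"]), float(row["d_sd"])


def run_grid(config: FMRConfig, predictions: dict | None = None,
             coefficients=None, constants=None) -> FMRResult:
    """Simulate daily FMR over the full covariate grid.

    Per-combination Monte Carlo draws use independent RNG substreams
    spawned from ``config.seed`` in fixed grid order, so matched
    comparisons are stable across configurations (e.g. rescaling H leaves
    every Cohen's d bit-identical).
    """
    combos = config.combos()
    if predictions is None:
        predictions = grid_predictions(config, coefficients, constants)
    missing = [i for i in range(len(combos)) if i not in predictions]
    if missing:
        raise ValidationError(f"missing predictions for combos {missing}")

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(combos))
    n = config.iterations
    fmr_draws, prey_draws = {}, {}
    rows = []
    for i, combo in enumerate(combos):
        rng = np.random.default_rng(streams[i])
        pred = predictions[i]
        lam = math.exp(pred["breath_count"].mu)
        tin_f = _foraging_tin_vec(
            lam, (pred["mean_ibi"].mu, pred["mean_ibi"].sigma),
            (pred["total_inhalation"].mu, pred["total_inhalation"].sigma),
            combo["dive_duration"], config.foraging_budget_s, rng, n)
        tin_t = _travel_tin_vec(
            (config.travel_hold_log_mean, config.travel_hold_log_sd),
            (config.travel_inhalation_log_mean,
             config.travel_inhalation_log_sd),
            config.travel_budget_s, rng, n)
        o2 = _draw_o2(rng, config.o2_extraction_mean,
                      config.o2_extraction_sd, n)
        vt = -7.24 + 2.14 * (tin_f + tin_t) * combo["tl"] ** 2
        fmr = config.h_mj_per_l_o2 * o2 * vt
        prey = fmr * 1000.0 / config.prey_energy_kj_per_g / 1e6
        fmr_draws[i] = fmr
        prey_draws[i] = prey
        lo, hi = np.percentile(fmr, [2.5, 97.5])
        plo, phi = np.percentile(prey, [2.5, 97.5])
        rows.append({**combo, "combo": i,
                     "fmr_mean_mj": float(fmr.mean()),
                     "fmr_lo_mj": float(lo), "fmr_hi_mj": float(hi),
                     "prey_mean_t": float(prey.mean()),
                     "prey_lo_t": float(plo), "prey_hi_t": float(phi)})
    combo_df = pd.DataFrame(rows)

    pair_rows = []
    axes = ("tl", "bai", "dive_duration", "tactic")
    index = {tuple(c[a] for a in axes): i for i, c in enumerate(combos)}
    for label, axis, lev_a, lev_b in COMPARISON_FAMILIES:
        for key, i in index.items():
            combo = dict(zip(axes, key))
            if combo[axis] != lev_a:
                continue
            partner = dict(combo)
            partner[axis] = lev_b
            j = index.get(tuple(partner[a] for a in axes))
            if j is None:
                continue
            d = cohens_d(fmr_draws[i], fmr_draws[j])
            pair_rows.append({
                "family": label, "combo_a": i, "combo_b": j, "d": d,
                "fmr_diff_mj": float(fmr_draws[i].mean()
                                     - fmr_draws[j].mean()),
                "prey_diff_t": float(prey_draws[i].mean()
                                     - prey_draws[j].mean()),
            })
    pairwise = pd.DataFrame(pair_rows)
    fam_rows = []
    for label, *_ in COMPARISON_FAMILIES:
        sub = pairwise[pairwise["family"] == label]
        if sub.empty:
            continue
        fam_rows.append({
            "family": label, "n_pairs": len(sub),
            "d_mean": float(sub["d"].mean()),
            "d_sd": float(sub["d"].std(ddof=1)),
            "fmr_diff_mean_mj": float(sub["fmr_diff_mj"].mean()),
            "fmr_diff_sd_mj": float(sub["fmr_diff_mj"].std(ddof=1)),
            "prey_diff_mean_t": float(sub["prey_diff_t"].mean()),
            "prey_diff_sd_t": float(sub["prey_diff_t"].std(ddof=1)),
        })
    return FMRResult(config=config, combos=combo_df, fmr_draws=fmr_draws,
                     prey_draws=prey_draws, pairwise=pairwise,
                     comparisons=pd.DataFrame(fam_rows))
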