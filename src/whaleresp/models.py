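"""Bayesian mixed models of respiration with covariate measurement error.

The model family mirrors how breath-by-breath respiration metrics are
analysed for foraging whales: each sequence-level response (breath count,
total inhalation duration, mean IBI, inhalation accumulation rate, initial /
terminal breath duration, travel respiration rate) is regressed on total
length (TL), body-area index (BAI), dive duration, bubble-blast occurrence,
and foraging tactic, with an individual random intercept.  Breath counts use
a Poisson log-link (zero-truncated by default, since a surfacing implies at
least one breath); continuous responses are Gaussian on the natural-log
scale.

Designs differ in *timing*: recovery designs take dive covariates from the
dive preceding the surface sequence, anticipation designs from the dive
following it, and the combined design keeps only sequences whose preceding
and following tactics match (including both dive durations, no bubble
covariate).  TL and BAI are measured with photogrammetric uncertainty, so
their true values are latent parameters with independent normal priors at
each unit's reported mean/sd and are imputed within the model.

Continuous covariates are z-scored; the constants are stored with every fit
and are required for prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ValidationError
from ._mcmc import run_chain_gaussian, run_chain_poisson

__all__ = [
    "ModelDesign",
    "DESIGNS",
    "StandardizationConstants",
    "Priors",
    "ModelData",
    "PosteriorFit",
    "DiagnosticsError",
    "zscore",
    "build_dataset",
    "fit_model",
    "coefficient_summary",
    "bayes_r2",
    "dispersion_stat",
    "residual_acf",
    "predict_response",
    "PredictedResponse",
]

REFERENCE_TACTIC = "headstand"


class DiagnosticsError(RuntimeError):
    """Raised when a fit fails its convergence contract."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class ModelDesign:
    """One model: response, error structure, timing, and fixed effects."""

    name: str
    response: str                 # column of the metrics table
    family: str                   # "poisson" | "lognormal"
    timing: str                   # recovery | anticipation | combined | travel
    fixed_effects: tuple
    truncated: bool = True        # poisson only: zero-truncated likelihood

    def __post_init__(self):
        if self.family not in ("poisson", "lognormal"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.timing not in ("recovery", "anticipation", "combined",
                               "travel"):
            raise ValidationError(f"unknown timing {self.timing!r}")


_FORAGE_FX = ("tl", "bai", "dive_duration", "bubble", "tactic")
_COMBINED_FX = ("tl", "bai", "dive_duration_preceding",
                "dive_duration_following", "tactic")

DESIGNS: dict[str, ModelDesign] = {d.name: d for d in [
    ModelDesign("recovery_breath_count", "breath_count", "poisson",
                "recovery", _FORAGE_FX),
    ModelDesign("recovery_total_inhalation", "total_inhalation_s",
                "lognormal", "recovery", _FORAGE_FX),
    ModelDesign("recovery_mean_ibi", "mean_ibi_s", "lognormal",
                "recovery", _FORAGE_FX),
    ModelDesign("recovery_accumulation_rate", "accumulation_rate",
                "lognormal", "recovery", _FORAGE_FX),
    ModelDesign("recovery_initial_breath", "initial_inhalation_s",
                "lognormal", "recovery", _FORAGE_FX),
    ModelDesign("anticipation_total_inhalation", "total_inhalation_s",
                "lognormal", "anticipation", _FORAGE_FX),
    ModelDesign("anticipation_mean_ibi", "mean_ibi_s", "lognormal",
                "anticipation", _FORAGE_FX),
    ModelDesign("anticipation_accumulation_rate", "accumulation_rate",
                "lognormal", "anticipation", _FORAGE_FX),
    ModelDesign("anticipation_terminal_breath", "terminal_inhalation_s",
                "lognormal", "anticipation", _FORAGE_FX),
    ModelDesign("combined_total_inhalation", "total_inhalation_s",
                "lognormal", "combined", _COMBINED_FX),
    ModelDesign("combined_mean_ibi", "mean_ibi_s", "lognormal",
                "combined", _COMBINED_FX),
    ModelDesign("combined_accumulation_rate", "accumulation_rate",
                "lognormal", "combined", _COMBINED_FX),
    ModelDesign("travel_respiration_rate", "respiration_rate_bpm",
                "lognormal", "travel", ("tl", "bai", "swim_speed")),
]}


@dataclass
class StandardizationConstants:
    """Per-covariate (mean, sd) pairs used for z-scoring."""

    values: dict = field(default_factory=dict)

    def get(self, name):
        return self.values.get(name)

    def set(self, name, mean, sd):
        if sd <= 0:
            raise ValidationError(f"z-scoring sd for {name!r} must be > 0")
        self.values[name] = (float(mean), float(sd))


def zscore(values, constants=None):
    """Standardize values; returns ``(z, (mean, sd))``.

    When ``constants`` is None the sample mean and sd (n-1 denominator) are
    computed from the data; otherwise the given constants are applied.
    """
    x = np.asarray(values, float)
    if constants is None:
        if np.unique(x[~np.isnan(x)]).size < 2:
            raise ValidationError(
                "need >= 2 distinct values to compute z-scoring constants")
        mean = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
    else:
        mean, sd = constants
    if sd <= 0:
        raise ValidationError("z-scoring sd must be positive")
    return (x - mean) / sd, (mean, sd)


@dataclass
class Priors:
    """Weakly informative defaults: Normal(0,1) slopes and tactic contrasts,
    Normal(data center, 2) intercept, Exponential(1) sds."""

    slope_sd: float = 1.0
    intercept_sd: float = 2.0
    intercept_center: float | None = None
    sd_rate: float = 1.0


@dataclass
class MCMCSettings:
    chains: int = 3
    iterations: int = 6500
    warmup: int = 1500
    seed: int = 0

    @classmethod
    def production_foraging(cls, seed=0):
        return cls(chains=3, iterations=90_000, warmup=30_000, seed=seed)

    @classmethod
    def production_travel(cls, seed=0):
        return cls(chains=3, iterations=30_000, warmup=10_000, seed=seed)


@dataclass
class ModelData:
    """Model-ready arrays for one design."""

    design: ModelDesign
    y: np.ndarray
    X: np.ndarray
    colnames: list
    whale_idx: np.ndarray
    whale_ids: list
    constants: StandardizationConstants
    frame: pd.DataFrame
    tl_prior: tuple | None = None     # (unit_idx, mean, sd)
    bai_prior: tuple | None = None

    @property
    def n_per_whale(self):
        return np.bincount(self.whale_idx, minlength=len(self.whale_ids))

    def latent_blocks(self):
        blocks = []
        for name, prior in (("tl", self.tl_prior), ("bai", self.bai_prior)):
            if prior is None or name not in self.colnames:
                continue
            unit_idx, mean_arr, sd_arr = prior
            m, s = self.constants.get(name)
            blocks.append(dict(col=self.colnames.index(name),
                               unit_idx=unit_idx, prior_mean=mean_arr,
                               prior_sd=sd_arr, mean=m, sd=s))
        return blocks


def _timing_cols(timing):
    if timing == "recovery":
        return {"dive_duration": "preceding_dive_duration_s",
                "bubble": "preceding_bubble_blast",
                "tactic": "preceding_tactic"}
    if timing == "anticipation":
        return {"dive_duration": "following_dive_duration_s",
                "bubble": "following_bubble_blast",
                "tactic": "following_tactic"}
    if timing == "combined":
        return {"dive_duration_preceding": "preceding_dive_duration_s",
                "dive_duration_following": "following_dive_duration_s",
                "tactic": "preceding_tactic"}
    return {}


def build_dataset(design: ModelDesign | str, metrics: pd.DataFrame,
                  morph: pd.DataFrame,
                  constants: StandardizationConstants | None = None,
                  ) -> ModelData:
    """Assemble the model-ready table for one design.

    ``metrics`` is a per-sequence metrics table (see
    :func:`whaleresp.metrics.sequence_table`) or, for the travel design, a
    travel-observation table.  ``morph`` carries one row per whale with
    ``tl_mean_m``/``tl_sd_m`` and ``bai_mean``/``bai_sd`` measurement
    posteriors.  Rows whose response or required covariates are missing are
    dropped (e.g. single-breath sequences have no IBI); the combined design
    additionally keeps only sequences whose preceding and following tactics
    match.  Continuous responses are natural-log transformed.
    """
    if isinstance(design, str):
        if design not in DESIGNS:
            raise ValidationError(f"unknown design {design!r}")
        design = DESIGNS[design]
    df = metrics.copy()

    if design.timing == "travel":
        df["respiration_rate_bpm"] = (60.0 * df["breath_count"]
                                      / df["travel_duration_s"])
    cols = _timing_cols(design.timing)
    if design.timing == "combined":
        df = df[df["preceding_tactic"].notna()
                & df["following_tactic"].notna()
                & (df["preceding_tactic"] == df["following_tactic"])]

    needed = [design.response] + [cols[f] for f in design.fixed_effects
                                  if f in cols]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if design.response not in df.columns:
        raise ValidationError(f"metrics table lacks {design.response!r}")
    df = df.merge(morph[["whale_id", "tl_mean_m", "tl_sd_m",
                         "bai_mean", "bai_sd"]], on="whale_id", how="inner")
    if df.empty:
        raise ValidationError("no rows left after filtering")
    df = df.reset_index(drop=True)

    if design.family == "poisson":
        y = df[design.response].to_numpy(float)
        if np.any(y < 1) and design.truncated:
            raise ValidationError("zero counts under a truncated likelihood")
    else:
        vals = df[design.response].to_numpy(float)
        if np.any(vals <= 0):
            raise ValidationError(
                f"{design.response} must be positive for a log response")
        y = np.log(vals)

    constants = constants or StandardizationConstants()
    colnames = ["intercept"]
    Xcols = [np.ones(len(df))]

    def add_continuous(name, values):
        if constants.get(name) is None:
            _, (m, s) = zscore(values)
            constants.set(name, m, s)
        z, _ = zscore(values, constants.get(name))
        colnames.append(name)
        Xcols.append(z)

    whale_ids = sorted(df["whale_id"].unique())
    wmap = {w: i for i, w in enumerate(whale_ids)}
    whale_idx = df["whale_id"].map(wmap).to_numpy()

    tl_prior = bai_prior = None
    for f in design.fixed_effects:
        if f == "tl":
            add_continuous("tl", df["tl_mean_m"].to_numpy(float))
            by_whale = df.groupby("whale_id")[["tl_mean_m", "tl_sd_m"]].first()
            tl_prior = (whale_idx,
                        by_whale.loc[whale_ids, "tl_mean_m"].to_numpy(),
                        by_whale.loc[whale_ids, "tl_sd_m"].to_numpy())
        elif f == "bai":
            add_continuous("bai", df["bai_mean"].to_numpy(float))
            by_whale = df.groupby("whale_id")[["bai_mean", "bai_sd"]].first()
            bai_prior = (whale_idx,
                         by_whale.loc[whale_ids, "bai_mean"].to_numpy(),
                         by_whale.loc[whale_ids, "bai_sd"].to_numpy())
        elif f in ("dive_duration", "dive_duration_preceding",
                   "dive_duration_following"):
            add_continuous(f, df[cols[f]].to_numpy(float))
        elif f == "swim_speed":
            add_continuous("swim_speed", df["swim_speed_ms"].to_numpy(float))
        elif f == "bubble":
            colnames.append("bubble")
            Xcols.append(df[cols["bubble"]].astype(float).to_numpy())
        elif f == "tactic":
            tactics = df[cols["tactic"]].astype(str)
            for level in sorted(tactics.unique()):
                if level == REFERENCE_TACTIC:
                    continue
                colnames.append(f"tactic[{level}]")
                Xcols.append((tactics == level).to_numpy(float))
        else:
            raise ValidationError(f"unknown fixed effect {f!r}")

    X = np.column_stack(Xcols)
    return ModelData(design=design, y=y, X=X, colnames=colnames,
                     whale_idx=whale_idx, whale_ids=whale_ids,
                     constants=constants, frame=df,
                     tl_prior=tl_prior, bai_prior=bai_prior)


@dataclass
class PosteriorFit:
    """Posterior draws plus everything needed to summarize and predict."""

    design: ModelDesign
    data: ModelData
    draws: dict                  # name -> array (chains, draws[, dim])
    constants: StandardizationConstants
    eta_mean: np.ndarray
    diagnostics: pd.DataFrame

    def stacked(self, name):
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def coefficient_means(self):
        beta = self.stacked("beta").mean(axis=0)
        return dict(zip(self.data.colnames, beta))

    @property
    def residual_sigma(self):
        if "sigma_resid" in self.draws:
            return float(self.stacked("sigma_resid").mean())
        return None


def fit_model(data: ModelData, priors: Priors | None = None,
              mcmc: MCMCSettings | None = None, check: bool = True,
              rhat_max: float = 1.01, ess_min: float = 400.0) -> PosteriorFit:
    """Fit one design by MCMC and verify the convergence contract.

    Runs ``mcmc.chains`` independent chains; reported parameters (fixed
    effects and sds) must reach R-hat < ``rhat_max`` and effective sample
    size > ``ess_min`` or a :class:`DiagnosticsError` is raised (disable
    with ``check=False`` for quick exploratory fits).
    """
    import arviz as az

    if data.y.size == 0:
        raise ValidationError("empty dataset")
    priors = priors or Priors()
    if mcmc is None:
        # the Metropolis-based Poisson chains need more iterations than the
        # mostly-Gibbs Gaussian chains for comparable effective sample sizes
        mcmc = (MCMCSettings(iterations=13000, warmup=2500)
                if data.design.family == "poisson"
                else MCMCSettings(iterations=4500, warmup=1000))
    if priors.intercept_center is None:
        center = (math.log(float(np.mean(data.y)))
                  if data.design.family == "poisson"
                  else float(np.mean(data.y)))
        priors = replace(priors, intercept_center=center)

    chains = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng([mcmc.seed, c])
        if data.design.family == "poisson":
            res = run_chain_poisson(data, priors, mcmc.iterations,
                                    mcmc.warmup, rng,
                                    truncated=data.design.truncated)
        else:
            res = run_chain_gaussian(data, priors, mcmc.iterations,
                                     mcmc.warmup, rng)
        chains.append(res)

    draws = {}
    for key in chains[0]:
        if key == "eta_mean":
            continue
        draws[key] = np.stack([c[key] for c in chains])
    eta_mean = np.mean([c["eta_mean"] for c in chains], axis=0)

    # diagnostics on the reported parameters
    named = {f"beta[{n}]": draws["beta"][:, :, i]
             for i, n in enumerate(data.colnames)}
    named["sigma_individual"] = draws["sigma_individual"]
    if "sigma_resid" in draws:
        named["sigma_resid"] = draws["sigma_resid"]
    idata = az.from_dict(posterior=named)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    report = pd.DataFrame({
        "parameter": list(named),
        "rhat": [float(rhat[k]) for k in named],
        "ess": [float(ess[k]) for k in named],
    })
    fit = PosteriorFit(design=data.design, data=data, draws=draws,
                       constants=data.constants, eta_mean=eta_mean,
                       diagnostics=report)
    if check:
        bad = report[(report["rhat"] >= rhat_max) | (report["ess"] <= ess_min)]
        if len(bad):
            raise DiagnosticsError(
                "convergence contract violated:\n" + bad.to_string(index=False),
                report=report)
    return fit


def coefficient_summary(fit_or_draws) -> pd.DataFrame:
    """Posterior mean, central 95% CrI, and percent of the posterior on the
    majority side of zero, per coefficient (plus sd summaries)."""
    if isinstance(fit_or_draws, PosteriorFit):
        items = {n: fit_or_draws.stacked("beta")[:, i]
                 for i, n in enumerate(fit_or_draws.data.colnames)}
        items["sigma_individual"] = fit_or_draws.stacked("sigma_individual")
        if "sigma_resid" in fit_or_draws.draws:
            items["sigma_resid"] = fit_or_draws.stacked("sigma_resid")
    else:
        items = {k: np.asarray(v, float).ravel()
                 for k, v in dict(fit_or_draws).items()}
    rows = []
    for name, x in items.items():
        if x.size < 4:
            raise ValidationError("too few draws to summarize")
        lo, hi = np.percentile(x, [2.5, 97.5])
        p_pos = float(np.mean(x > 0))
        rows.append({"coefficient": name, "mean": float(x.mean()),
                     "cri_lower": float(lo), "cri_upper": float(hi),
                     "pct_over_zero": 100.0 * max(p_pos, 1.0 - p_pos)})
    return pd.DataFrame(rows)


def bayes_r2(fit: PosteriorFit) -> dict:
    """Bayes R^2 on the link / log scale: per-draw
    var(fitted) / (var(fitted) + var(residual)); residual variance is
    sigma^2 for the Gaussian family and the delta-method mean(1/lambda) for
    the Poisson family."""
    vf = fit.stacked("var_fit")
    vr = fit.stacked("var_res")
    r2 = vf / (vf + vr)
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return {"mean": float(r2.mean()), "cri_lower": float(lo),
            "cri_upper": float(hi), "draws": r2}


def dispersion_stat(fit: PosteriorFit) -> float:
    """Posterior-mean Pearson dispersion: sum r_i^2 / (n - p)."""
    if fit.design.family != "poisson":
        raise ValidationError("dispersion is defined for Poisson fits only")
    n = fit.data.y.size
    p = len(fit.data.colnames)
    if n <= p:
        raise ValidationError("need more observations than parameters")
    return float(fit.stacked("pearson_chi2").mean() / (n - p))


def residual_acf(fit_or_residuals, lags: int = 10, order=None) -> pd.DataFrame:
    """Lag-1..K autocorrelations of posterior-mean residuals with approximate
    95% white-noise bands (+/- 1.96 / sqrt(n)).

    ``order`` optionally permutes residuals into within-deployment time
    order.  Constant residual series are undefined and flagged (NaN acf).
    """
    if isinstance(fit_or_residuals, PosteriorFit):
        fit = fit_or_residuals
        if fit.design.family == "poisson":
            lam = np.exp(fit.eta_mean)
            resid = (fit.data.y - lam) / np.sqrt(lam)
        else:
            resid = fit.data.y - fit.eta_mean
    else:
        resid = np.asarray(fit_or_residuals, float)
    if order is not None:
        resid = resid[np.asarray(order)]
    n = resid.size
    if n < lags + 2:
        raise ValidationError("series too short for requested lags")
    band = 1.96 / math.sqrt(n)
    c = resid - resid.mean()
    denom = float(c @ c)
    rows = []
    for k in range(1, lags + 1):
        acf = float(c[:-k] @ c[k:] / denom) if denom > 0 else float("nan")
        rows.append({"lag": k, "acf": acf, "band": band,
                     "exceeds_band": bool(denom > 0 and abs(acf) > band),
                     "degenerate": denom == 0})
    return pd.DataFrame(rows)


@dataclass
class PredictedResponse:
    """Response-scale prediction at one covariate combination."""

    family: str
    mu: float                    # linear predictor on the log/link scale
    sigma: float = 0.0           # lognormal log-sd (0 => point prediction)

    @property
    def mean(self):
        if self.family == "poisson":
            return math.exp(self.mu)
        return math.exp(self.mu + self.sigma ** 2 / 2.0)

    @property
    def median(self):
        return math.exp(self.mu)


def predict_response(source, combo: dict,
                     constants: StandardizationConstants | None = None,
                     family: str | None = None,
                     sigma: float | None = None) -> PredictedResponse:
    """Linear predictor at a covariate combination, on the response scale.

    ``source`` is a :class:`PosteriorFit` (posterior-mean coefficients, its
    own constants and residual sd) or a plain ``{term: value}`` coefficient
    mapping (then ``constants`` and ``family`` must be supplied).  The
    random intercept is set to zero.  ``combo`` gives covariates on their
    natural scales, e.g. ``{"tl": 12, "bai": 27, "dive_duration": 120,
    "tactic": "headstand", "bubble": False}``.
    """
    if isinstance(source, PosteriorFit):
        coefs = source.coefficient_means()
        constants = source.constants
        family = source.design.family
        if sigma is None:
            sigma = source.residual_sigma or 0.0
    else:
        coefs = dict(source)
        if constants is None or family is None:
            raise ValidationError(
                "plug-in prediction needs constants and family")
        sigma = 0.0 if sigma is None else sigma

    lp = coefs.get("intercept", 0.0)
    for name in ("tl", "bai", "dive_duration", "dive_duration_preceding",
                 "dive_duration_following", "swim_speed"):
        if name not in coefs:
            continue
        combo_key = ("dive_duration"
                     if name.startswith("dive_duration") else name)
        if combo_key not in combo:
            raise ValidationError(f"combo missing covariate {combo_key!r}")
        cst = constants.get(name)
        if cst is None:
            raise ValidationError(f"missing z-scoring constants for {name!r}")
        z, _ = zscore([combo[combo_key]], cst)
        lp += coefs[name] * float(z[0])
    if "bubble" in coefs:
        lp += coefs["bubble"] * float(bool(combo.get("bubble", False)))
    tactic = combo.get("tactic", REFERENCE_TACTIC)
    if tactic != REFERENCE_TACTIC:
        key = f"tactic[{tactic}]"
        lp += coefs.get(key, coefs.get(tactic, 0.0))
    return PredictedResponse(family=family, mu=float(lp), sigma=float(sigma))
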