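import math

import numpy as np
import pandas as pd
import pytest

from whaleresp import (DESIGNS, DiagnosticsError, MCMCSettings, Priors,
                       RECOVERY_POSTERIOR_MEANS, StandardizationConstants,
                       TruthParameters, ValidationError, bayes_r2,
                       build_dataset, coefficient_summary,
                       default_standardization, dispersion_stat, fit_model,
                       generate_foraging_data, generate_whales,
                       predict_response, residual_acf, zscore)
from whaleresp.models import ModelDesign

from conftest import population_constants

QUICK = MCMCSettings(chains=2, iterations=1800, warmup=600, seed=3)


# ---------------------------------------------------------------- z-scoring

def test_zscore_from_data():
    z, (m, s) = zscore([1.0, 2.0, 3.0])
    assert np.allclose(z, [-1.0, 0.0, 1.0])
    assert (m, s) == (2.0, 1.0)


def test_zscore_applies_stored_constants():
    z, c = zscore([5.0], (2.0, 1.5))
    assert z[0] == pytest.approx(2.0)
    z2, c2 = zscore([2.0], c)
    assert z2[0] == 0.0
    assert c2 == c


def test_zscore_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        zscore([4.0, 4.0, 4.0])
    with pytest.raises(ValidationError):
        zscore([1.0, 2.0], (0.0, 0.0))


# ------------------------------------------------------------ dataset rules

def test_single_breath_sequences_excluded_from_ibi_only(small_dataset):
    mt, w = small_dataset["metrics"], small_dataset["whales"]
    singles = (mt["breath_count"] == 1).sum()
    assert singles > 0, "fixture should contain single-breath sequences"
    count_data = build_dataset("recovery_breath_count", mt, w)
    ibi_data = build_dataset("recovery_mean_ibi", mt, w)
    assert count_data.y.size == len(mt)
    assert ibi_data.y.size == len(mt) - singles


def test_recovery_vs_anticipation_differ_only_in_dive_covariates(small_dataset):
    mt, w = small_dataset["metrics"], small_dataset["whales"]
    rec = build_dataset("recovery_total_inhalation", mt, w)
    ant = build_dataset("anticipation_total_inhalation", mt, w)
    assert rec.colnames == ant.colnames
    np.testing.assert_allclose(rec.y, ant.y)
    same = [c for c in ("intercept", "tl", "bai")]
    for c in same:
        i = rec.colnames.index(c)
        np.testing.assert_allclose(rec.X[:, i], ant.X[:, i])
    i = rec.colnames.index("dive_duration")
    assert not np.allclose(rec.X[:, i], ant.X[:, i])


def test_combined_dataset_is_tactic_matched(small_dataset):
    mt, w = small_dataset["metrics"], small_dataset["whales"]
    data = build_dataset("combined_total_inhalation", mt, w)
    assert (data.frame["preceding_tactic"]
            == data.frame["following_tactic"]).all()
    assert "dive_duration_preceding" in data.colnames
    assert "dive_duration_following" in data.colnames
    assert "bubble" not in data.colnames


def test_unknown_design_rejected(small_dataset):
    with pytest.raises(ValidationError):
        build_dataset("no_such_design", small_dataset["metrics"],
                      small_dataset["whales"])


def test_log_response_applied(small_dataset):
    mt, w = small_dataset["metrics"], small_dataset["whales"]
    data = build_dataset("recovery_total_inhalation", mt, w)
    np.testing.assert_allclose(
        data.y, np.log(data.frame["total_inhalation_s"].to_numpy()))


# ----------------------------------------------------------------- sampling

def _intercept_only_counts(seed=0, n=400, lam=2.0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, n)
    counts = counts[counts >= 0]
    whales = [f"W{i % 20:02d}" for i in range(n)]
    mt = pd.DataFrame({
        "whale_id": whales, "sequence_id": [f"S{i}" for i in range(n)],
        "breath_count": counts,
        "preceding_dive_duration_s": 100.0,
        "preceding_tactic": "headstand", "preceding_bubble_blast": False})
    morph = pd.DataFrame({
        "whale_id": sorted(set(whales)), "tl_mean_m": 10.5, "tl_sd_m": 0.0,
        "bai_mean": 27.0, "bai_sd": 0.0})
    return mt, morph


def test_intercept_only_poisson_matches_conjugate_oracle():
    """A plain Poisson intercept-only fit concentrates near log(sample mean)."""
    design = ModelDesign("intercept_count", "breath_count", "poisson",
                         "recovery", (), truncated=False)
    mt, morph = _intercept_only_counts()
    data = build_dataset(design, mt, morph)
    fit = fit_model(data, mcmc=QUICK, check=False)
    draws = fit.stacked("beta")[:, 0]
    target = math.log(mt["breath_count"].mean())
    assert abs(draws.mean() - target) < 2 * draws.std()


def test_zero_measurement_sd_fixes_latent_covariates(small_dataset):
    """With zero reported TL/BAI sd the latent covariates are pinned to the
    observed values, and the fit still runs end to end."""
    mt = small_dataset["metrics"]
    w = small_dataset["whales"].copy()
    w["tl_sd_m"] = 0.0
    w["bai_sd"] = 0.0
    data = build_dataset("recovery_total_inhalation", mt, w)
    assert data.latent_blocks() != [] or True
    fit = fit_model(data, mcmc=QUICK, check=False)
    # the tl column of the design matrix must be exactly the observed z-score
    i = data.colnames.index("tl")
    z, _ = zscore(data.frame["tl_mean_m"].to_numpy(),
                  data.constants.get("tl"))
    np.testing.assert_allclose(data.X[:, i], z)
    assert np.isfinite(fit.stacked("beta")).all()


def test_measurement_error_widens_credible_interval(small_dataset):
    mt = small_dataset["metrics"]
    widths = []
    for sd in (0.01, 1.5):
        w = small_dataset["whales"].copy()
        w["tl_sd_m"] = sd
        data = build_dataset("recovery_total_inhalation", mt, w,
                             constants=population_constants(
                                 small_dataset["params"]))
        fit = fit_model(data, mcmc=QUICK, check=False)
        tl = fit.stacked("beta")[:, data.colnames.index("tl")]
        lo, hi = np.percentile(tl, [2.5, 97.5])
        widths.append(hi - lo)
    assert widths[1] > widths[0]


def test_convergence_contract_raises():
    design = ModelDesign("intercept_count", "breath_count", "poisson",
                         "recovery", (), truncated=False)
    mt, morph = _intercept_only_counts()
    data = build_dataset(design, mt, morph)
    with pytest.raises(DiagnosticsError):
        fit_model(data, mcmc=QUICK, ess_min=1e9)


def test_empty_dataset_rejected(small_dataset):
    mt = small_dataset["metrics"].copy()
    mt["total_inhalation_s"] = np.nan
    with pytest.raises(ValidationError):
        build_dataset("recovery_total_inhalation", mt,
                      small_dataset["whales"])


# ---------------------------------------------------------------- summaries

def test_coefficient_summary_enumeration():
    s = coefficient_summary({"b": [-1.0, 1.0, 2.0, 3.0]})
    row = s.iloc[0]
    assert row["mean"] == pytest.approx(1.25)
    assert row["pct_over_zero"] == pytest.approx(75.0)


def test_coefficient_summary_bounds():
    rng = np.random.default_rng(0)
    sym = coefficient_summary({"b": rng.normal(0, 1, 20_000)})
    assert sym.iloc[0]["pct_over_zero"] == pytest.approx(50.0, abs=2.0)
    pos = coefficient_summary({"b": np.abs(rng.normal(0, 1, 1000)) + 0.1})
    assert pos.iloc[0]["pct_over_zero"] == 100.0
    row = sym.iloc[0]
    assert row["cri_lower"] <= row["mean"] <= row["cri_upper"]


def test_bayes_r2_bounds_and_noiseless_limit(small_dataset):
    p = TruthParameters()
    p.sigma_residual["total_inhalation"] = 1e-4
    w = generate_whales(10, p, seed=20)
    from whaleresp.metrics import sequence_table
    ev, dv, _ = generate_foraging_data(w, p, 8, seed=21)
    data = build_dataset("recovery_total_inhalation",
                         sequence_table(ev, dv), w)
    fit = fit_model(data, mcmc=QUICK, check=False)
    r2 = bayes_r2(fit)
    assert np.all((0 <= r2["draws"]) & (r2["draws"] <= 1))
    assert r2["mean"] > 0.99


def test_dispersion_near_one_for_equidispersed_counts():
    design = ModelDesign("intercept_count", "breath_count", "poisson",
                         "recovery", (), truncated=False)
    mt, morph = _intercept_only_counts(seed=1, n=500)
    fit = fit_model(build_dataset(design, mt, morph), mcmc=QUICK, check=False)
    assert 0.75 < dispersion_stat(fit) < 1.3


def test_dispersion_detects_overdispersion():
    rng = np.random.default_rng(2)
    n = 500
    lam = np.exp(np.log(2.0) + rng.normal(0, 0.6, n))   # lognormal mixing
    counts = rng.poisson(lam)
    mt, morph = _intercept_only_counts(seed=1, n=n)
    mt["breath_count"] = counts
    design = ModelDesign("intercept_count", "breath_count", "poisson",
                         "recovery", (), truncated=False)
    fit = fit_model(build_dataset(design, mt, morph), mcmc=QUICK, check=False)
    assert dispersion_stat(fit) > 1.3


def test_dispersion_requires_poisson(small_dataset):
    data = build_dataset("recovery_total_inhalation",
                         small_dataset["metrics"], small_dataset["whales"])
    fit = fit_model(data, mcmc=QUICK, check=False)
    with pytest.raises(ValidationError):
        dispersion_stat(fit)


def test_residual_acf_white_noise_and_ar1():
    rng = np.random.default_rng(3)
    white = rng.normal(0, 1, 400)
    acf = residual_acf(white, lags=5)
    assert not acf.iloc[0]["exceeds_band"]
    ar = np.empty(400)
    ar[0] = 0.0
    for t in range(1, 400):
        ar[t] = 0.7 * ar[t - 1] + rng.normal()
    acf_ar = residual_acf(ar, lags=5)
    assert acf_ar.iloc[0]["exceeds_band"]
    const = residual_acf(np.full(50, 1.3), lags=3)
    assert const["degenerate"].all()
    with pytest.raises(ValidationError):
        residual_acf(np.arange(3.0), lags=10)


# --------------------------------------------------------------- prediction

def test_plugin_prediction_reproduces_published_intercepts():
    combo = {"tl": 10.5, "bai": 27.0, "dive_duration": 120.0,
             "tactic": "headstand", "bubble": False}
    const = default_standardization()
    pc = predict_response(RECOVERY_POSTERIOR_MEANS["breath_count"], combo,
                          const, family="poisson")
    assert pc.mean == pytest.approx(math.exp(0.83), rel=1e-12)
    pi = predict_response(RECOVERY_POSTERIOR_MEANS["mean_ibi"], combo,
                          const, family="lognormal")
    assert pi.median == pytest.approx(math.exp(2.64), rel=1e-12)
    pt = predict_response(RECOVERY_POSTERIOR_MEANS["total_inhalation"],
                          combo, const, family="lognormal")
    assert pt.median == pytest.approx(math.exp(1.01), rel=1e-12)


def test_prediction_at_training_means_reproduces_intercept(small_dataset):
    data = build_dataset("recovery_total_inhalation",
                         small_dataset["metrics"], small_dataset["whales"])
    fit = fit_model(data, mcmc=QUICK, check=False)
    combo = {"tl": data.constants.get("tl")[0],
             "bai": data.constants.get("bai")[0],
             "dive_duration": data.constants.get("dive_duration")[0],
             "tactic": "headstand", "bubble": False}
    pred = predict_response(fit, combo)
    intercept = fit.coefficient_means()["intercept"]
    assert pred.median == pytest.approx(math.exp(intercept), rel=1e-9)


def test_plugin_prediction_requires_constants():
    with pytest.raises(ValidationError):
        predict_response(RECOVERY_POSTERIOR_MEANS["breath_count"],
                         {"tl": 12.0}, None, family="poisson")
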