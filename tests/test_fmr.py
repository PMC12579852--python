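import math

import numpy as np
import pytest

from whaleresp import (FMRConfig, ValidationError, cohens_d, fmr_daily,
                       grid_predictions, prey_requirement, run_grid,
                       simulate_day, simulate_foraging_period,
                       simulate_travel_period, tidal_volume_daily)
from whaleresp.fmr import COMPARISON_FAMILIES


def test_config_invariants():
    with pytest.raises(ValidationError):
        FMRConfig(activity_budget={"forage": 0.5, "search": 0.4,
                                   "travel": 0.2})
    with pytest.raises(ValidationError):
        FMRConfig(o2_extraction_sd=0.0)
    assert len(FMRConfig().combos()) == 36


@pytest.mark.parametrize("tin,tl,expected", [
    (1.0, 12.0, 300.92),
    (0.0, 9.0, -7.24),                  # nonphysical intercept regime
    (1000.0, 9.0, 173_332.76),
])
def test_tidal_volume_direct_evaluation(tin, tl, expected):
    assert tidal_volume_daily(tin, tl) == pytest.approx(expected, rel=1e-12)


def test_tidal_volume_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        tidal_volume_daily(-1.0, 10.0)
    with pytest.raises(ValidationError):
        tidal_volume_daily(1.0, 0.0)


def test_fmr_daily_arithmetic_and_linearity():
    assert fmr_daily(0.002, 0.11, 300.92) == pytest.approx(0.0662024)
    assert fmr_daily(0.002, 0.11, 0.0) == 0.0
    assert fmr_daily(0.004, 0.11, 300.92) == pytest.approx(
        2 * fmr_daily(0.002, 0.11, 300.92))
    with pytest.raises(ValidationError):
        fmr_daily(0.002, 1.5, 100.0)


def test_prey_requirement_units():
    assert prey_requirement(191.0, 1.91) == pytest.approx(0.1)
    assert prey_requirement(0.0) == 0.0
    assert prey_requirement(382.0, 1.91) == pytest.approx(0.2)
    with pytest.raises(ValidationError):
        prey_requirement(10.0, 0.0)


def test_cohens_d_formula_and_antisymmetry():
    rng = np.random.default_rng(0)
    a = rng.normal(3.0, 1.0, 5000)
    b = rng.normal(1.0, 1.0, 5000)
    assert cohens_d(a, b) == pytest.approx(2.0, abs=0.1)
    assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-12)
    assert cohens_d(a, a) == 0.0
    with pytest.raises(ValidationError):
        cohens_d([1.0, 1.0], [1.0, 1.0])


def test_foraging_period_degenerate_closed_form():
    rng = np.random.default_rng(0)
    res = simulate_foraging_period(
        count_mean=2.0, ibi=(math.log(14.0), 0.0),
        t_in=(math.log(2.75), 0.0), dive_duration_s=60.0,
        budget_s=31_104.0, rng=rng, fixed_count=2)
    assert res.n_cycles == 343            # ceil(31104 / 90.75)
    assert res.t_in_s == 343 * 2.75
    zero = simulate_foraging_period(2.0, (0.0, 0.0), (0.0, 0.0), 60.0,
                                    0.0, rng)
    assert (zero.t_in_s, zero.n_cycles) == (0.0, 0)


def test_foraging_period_renewal_mean():
    rng = np.random.default_rng(1)
    lam, ibi, tin = 2.3, (2.64, 0.3), (1.01, 0.3)
    dive, budget = 120.0, 500_000.0
    res = simulate_foraging_period(lam, ibi, tin, dive, budget, rng)
    mean_count = lam / (1 - math.exp(-lam))
    mean_cycle = (dive + mean_count * math.exp(ibi[0] + ibi[1] ** 2 / 2)
                  + math.exp(tin[0] + tin[1] ** 2 / 2))
    expected = budget / mean_cycle
    assert abs(res.n_cycles - expected) < 3 * math.sqrt(expected)


def test_travel_period_degenerate_closed_form():
    rng = np.random.default_rng(0)
    res = simulate_travel_period((math.log(48.0), 0.0), (math.log(1.5), 0.0),
                                 1000.0, rng)
    n = math.ceil(1000.0 / 49.5)
    assert res.n_cycles == n
    assert res.t_in_s == pytest.approx(n * 1.5, rel=1e-12)
    assert simulate_travel_period((1.0, 0.5), (0.1, 0.1), 0.0, rng).t_in_s == 0.0


def test_travel_lognormal_sampling_mean_hold():
    """Mean simulated breath hold matches exp(3.66 + 0.65^2/2) ~= 48.03 s."""
    rng = np.random.default_rng(2)
    hold = (3.66, 0.65)
    inh = (0.26, 0.17)
    mean_hold = math.exp(3.66 + 0.65 ** 2 / 2)
    mean_inh = math.exp(0.26 + 0.17 ** 2 / 2)
    budget = 10_000 * (mean_hold + mean_inh)
    res = simulate_travel_period(hold, inh, budget, rng)
    holds_mean = (res.duration_s - res.t_in_s) / res.n_cycles
    sd_hold = mean_hold * math.sqrt(math.exp(0.65 ** 2) - 1)
    assert abs(holds_mean - mean_hold) < 3 * sd_hold / math.sqrt(res.n_cycles)
    inh_mean = res.t_in_s / res.n_cycles
    sd_inh = mean_inh * math.sqrt(math.exp(0.17 ** 2) - 1)
    assert abs(inh_mean - mean_inh) < 3 * sd_inh / math.sqrt(res.n_cycles)


def test_simulate_day_requires_predictions():
    cfg = FMRConfig(iterations=10, seed=0)
    with pytest.raises(ValidationError):
        simulate_day({"tl": 9.0, "dive_duration": 60.0}, {},
                     cfg, np.random.default_rng(0))


def test_simulate_day_fmr_increases_with_tl():
    cfg = FMRConfig(seed=0)
    preds = grid_predictions(cfg)
    combos = cfg.combos()
    i9 = next(i for i, c in enumerate(combos)
              if c["tl"] == 9.0 and c["bai"] == 27.0
              and c["dive_duration"] == 120.0 and c["tactic"] == "headstand")
    i12 = next(i for i, c in enumerate(combos)
               if c["tl"] == 12.0 and c["bai"] == 27.0
               and c["dive_duration"] == 120.0 and c["tactic"] == "headstand")
    # same respiration predictions, differing TL: FMR must rise with TL^2
    rng = np.random.default_rng(5)
    fmr9, _ = simulate_day(combos[i9], preds[i12], cfg, rng)
    rng = np.random.default_rng(5)
    fmr12, _ = simulate_day(combos[i12], preds[i12], cfg, rng)
    assert fmr12 > fmr9


def test_grid_structure_and_pair_counts():
    cfg = FMRConfig(iterations=50, seed=3)
    res = run_grid(cfg)
    assert len(res.combos) == 36
    fam = res.comparisons.set_index("family")
    assert fam.loc["TL 12-9", "n_pairs"] == 18
    assert fam.loc["Tactic headstand-forward", "n_pairs"] == 18
    for label in ("BAI 27-22", "BAI 32-22", "BAI 32-27",
                  "Dive 120-300", "Dive 60-120", "Dive 60-300"):
        assert fam.loc[label, "n_pairs"] == 12


def test_family_d_mean_matches_pairwise_enumeration():
    cfg = FMRConfig(iterations=200, seed=4)
    res = run_grid(cfg)
    for label, axis, la, lb in COMPARISON_FAMILIES:
        sub = res.pairwise[res.pairwise["family"] == label]
        brute = [cohens_d(res.fmr_draws[int(r["combo_a"])],
                          res.fmr_draws[int(r["combo_b"])])
                 for _, r in sub.iterrows()]
        assert res.comparisons.set_index("family").loc[label, "d_mean"] == \
            pytest.approx(np.mean(brute), rel=1e-12)


def test_reproducibility_same_seed():
    cfg = FMRConfig(iterations=100, seed=9)
    r1 = run_grid(cfg)
    r2 = run_grid(cfg)
    for i in r1.fmr_draws:
        np.testing.assert_array_equal(r1.fmr_draws[i], r2.fmr_draws[i])
    assert r1.comparisons.equals(r2.comparisons)


def test_prey_draws_are_exact_conversion_of_fmr_draws():
    cfg = FMRConfig(iterations=100, seed=11)
    res = run_grid(cfg)
    for i in res.fmr_draws:
        np.testing.assert_allclose(
            res.prey_draws[i],
            res.fmr_draws[i] * 1000.0 / cfg.prey_energy_kj_per_g / 1e6,
            rtol=0, atol=0)
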