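import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from whaleresp import (BreathEvent, ValidationError, inhalation_duration,
                       match_bai, mean_swim_speed, standardized_nares_area,
                       summarize_sequence, travel_respiration_rate)
from whaleresp.metrics import EARTH_RADIUS_M, classify_breaths, sequence_table

from _oracles import brute_force_sequence_metrics, random_breath_sequence


def _seq(intervals, whale="W0", seq="S0"):
    return [BreathEvent(whale, seq, s, e) for s, e in intervals]


@pytest.mark.parametrize("start,end,expected", [
    (0.0, 2.4, 1.2),        # inhalation is half the visible blow duration
    (5.0, 5.0, 0.0),
    (10.0, 12.6, 1.3),
])
def test_inhalation_duration_is_half_breath(start, end, expected):
    assert inhalation_duration(BreathEvent("W", "S", start, end)) == pytest.approx(expected)


def test_inhalation_duration_rejects_reversed_interval():
    with pytest.raises(ValidationError):
        inhalation_duration((5.0, 4.0))


def test_three_breath_sequence_worked_example():
    m = summarize_sequence(_seq([(0, 2), (20, 22), (45, 47)]))
    assert m.breath_count == 3
    assert m.sequence_duration_s == 45.0
    assert m.total_inhalation_s == pytest.approx(3.0)
    assert m.mean_ibi_s == pytest.approx(20.5)       # gaps 18 and 23 s
    # OLS slope through (0,1), (20,2), (45,3): 45 / 1016.667
    assert m.accumulation_rate == pytest.approx(45.0 / (3050.0 / 3.0))
    assert m.accumulation_rate == pytest.approx(0.04426, abs=1e-5)


def test_single_breath_sequence_has_absent_metrics():
    m = summarize_sequence(_seq([(0, 2)]))
    assert m.breath_count == 1
    assert m.sequence_duration_s == 0.0
    assert m.mean_ibi_s is None
    assert m.accumulation_rate is None
    assert m.terminal_inhalation_s is None
    assert classify_breaths(1) == ["initial"]


def test_breath_classes_initial_middle_terminal():
    assert classify_breaths(3) == ["initial", "middle", "terminal"]
    assert classify_breaths(2) == ["initial", "terminal"]


def test_regular_breathing_slope_is_inhalation_over_period():
    d, T = 1.5, 25.0
    intervals = [(k * T, k * T + 2 * d) for k in range(5)]
    m = summarize_sequence(_seq(intervals))
    assert m.accumulation_rate == pytest.approx(d / T, rel=1e-12)


def test_unordered_breaths_rejected():
    with pytest.raises(ValidationError):
        summarize_sequence(_seq([(0, 5), (3, 6)]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_metrics_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    breaths = random_breath_sequence(rng)
    m = summarize_sequence(_seq(breaths))
    oracle = brute_force_sequence_metrics(breaths)
    assert m.breath_count == oracle["breath_count"]
    for field in ("sequence_duration_s", "total_inhalation_s",
                  "initial_inhalation_s", "mean_ibi_s",
                  "accumulation_rate", "terminal_inhalation_s"):
        got, want = getattr(m, field), oracle[field]
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000),
       st.floats(-1e5, 1e5, allow_nan=False))
def test_accumulation_slope_invariant_to_time_shift(seed, shift):
    rng = np.random.default_rng(seed)
    breaths = random_breath_sequence(rng)
    if len(breaths) < 2:
        breaths = breaths + [(breaths[0][1] + 10, breaths[0][1] + 12)]
    shifted = [(s + shift, e + shift) for s, e in breaths]
    m0 = summarize_sequence(_seq(breaths))
    m1 = summarize_sequence(_seq(shifted))
    assert m1.accumulation_rate == pytest.approx(m0.accumulation_rate,
                                                 rel=1e-6, abs=1e-12)


@pytest.mark.parametrize("count,duration,expected", [
    (12, 600.0, 1.2),
    (0, 600.0, 0.0),
    (7, 210.0, 2.0),
])
def test_travel_respiration_rate(count, duration, expected):
    assert travel_respiration_rate(count, duration) == pytest.approx(expected)


def test_travel_respiration_rate_rejects_zero_duration():
    with pytest.raises(ValidationError):
        travel_respiration_rate(3, 0.0)


def test_swim_speed_zero_for_identical_fixes():
    fixes = pd.DataFrame({"time_s": [0, 5], "lat": [44.6, 44.6],
                          "lon": [-124.1, -124.1]})
    assert mean_swim_speed(fixes) == 0.0


def test_swim_speed_matches_great_circle_oracle():
    # two fixes differing only in latitude: distance is exactly R * dphi
    dphi = 10.0 / EARTH_RADIUS_M
    fixes = pd.DataFrame({
        "time_s": [0.0, 5.0],
        "lat": [44.6, 44.6 + math.degrees(dphi)],
        "lon": [-124.1, -124.1]})
    assert mean_swim_speed(fixes) == pytest.approx(2.0, rel=1e-9)


def test_swim_speed_consistent_for_collinear_fixes():
    dphi = 20.0 / EARTH_RADIUS_M
    lat = [10.0 + math.degrees(dphi) * k for k in range(3)]
    fixes = pd.DataFrame({"time_s": [0.0, 5.0, 10.0], "lat": lat,
                          "lon": [0.0] * 3})
    seg = mean_swim_speed(fixes.iloc[:2])
    assert mean_swim_speed(fixes) == pytest.approx(seg, rel=1e-9)
    with pytest.raises(ValidationError):
        mean_swim_speed(fixes.iloc[:1])


def _bai_series(dates):
    return pd.DataFrame({"whale_id": "W0", "date": pd.to_datetime(dates),
                         "bai_mean": np.arange(len(dates), dtype=float),
                         "bai_sd": 1.0})


def test_match_bai_prefers_same_day():
    series = _bai_series(["2022-07-10", "2022-07-15"])
    assert match_bai("2022-07-15", series)["bai_mean"] == 1.0


def test_match_bai_window_boundary():
    series = _bai_series(["2022-07-01"])
    assert match_bai("2022-07-15", series)["bai_mean"] == 0.0   # 14 days
    assert match_bai("2022-07-16", series) is None              # 15 days


def test_match_bai_tie_goes_to_earlier_date():
    series = _bai_series(["2022-07-12", "2022-07-18"])
    assert match_bai("2022-07-15", series)["bai_mean"] == 0.0


@pytest.mark.parametrize("area,tl,expected", [
    (0.0, 8.0, 0.0),
    (0.0030, 10.0, 3.0e-4),
])
def test_standardized_nares_area(area, tl, expected):
    assert standardized_nares_area(area, tl) == pytest.approx(expected)


def test_standardized_nares_area_homogeneity_and_errors():
    assert standardized_nares_area(0.004, 12.0) == pytest.approx(
        2 * standardized_nares_area(0.004, 24.0))
    assert standardized_nares_area(0.004, 10.0, exponent=2) == pytest.approx(
        4.0e-5)
    with pytest.raises(ValidationError):
        standardized_nares_area(0.004, 0.0)


def test_count_and_total_inhalation_strongly_correlated(small_dataset):
    """The generator reproduces the strong field correlation between breath
    count and total inhalation duration."""
    mt = small_dataset["metrics"]
    r = np.corrcoef(mt["breath_count"], mt["total_inhalation_s"])[0, 1]
    assert r > 0.9


def test_sequence_table_attaches_dive_context(small_dataset):
    mt = small_dataset["metrics"]
    man = small_dataset["manifest"].sequences
    j = mt.merge(man[["sequence_id", "preceding_dive_id"]],
                 on="sequence_id", suffixes=("", "_truth"))
    assert (j["preceding_dive_id"] == j["preceding_dive_id_truth"]).all()
    assert j["following_tactic"].notna().all()
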