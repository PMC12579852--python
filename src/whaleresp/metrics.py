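"""Drone-derived respiration metrics for surface sequences.

A *surface sequence* is the period from the first breath after a dive to the
final breath before the next dive.  For each annotated breath only the start
and end of the visible blow are recorded; inhalation duration is taken as
one-half of that breath duration (inhalation and exhalation durations are
equal in gray whales).  Sequence-level metrics:

- sequence duration: seconds from the start of the initial breath to the
  start of the terminal breath;
- breath count, total inhalation duration (sum of per-breath inhalations);
- mean inter-breath interval (IBI): mean end-to-start gap between sequential
  breaths (absent for single-breath sequences);
- inhalation accumulation rate: ordinary-least-squares slope of cumulative
  inhalation duration against seconds since the first breath — a proxy for
  how quickly oxygen is being accumulated during recovery;
- initial / terminal breath inhalation durations.

Metrics that are undefined for a sequence (e.g. IBI with one breath) are
emitted as missing, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "BreathEvent",
    "SequenceMetrics",
    "inhalation_duration",
    "classify_breaths",
    "summarize_sequence",
    "sequence_table",
    "travel_respiration_rate",
    "mean_swim_speed",
    "match_bai",
    "standardized_nares_area",
]

EARTH_RADIUS_M = 6371008.8


@dataclass(frozen=True)
class BreathEvent:
    whale_id: str
    sequence_id: str
    start_s: float
    end_s: float
    breath_class: str | None = None
    naris_area_m2: float | None = None

    def __post_init__(self):
        if self.end_s < self.start_s:
            raise ValidationError(
                f"breath end ({self.end_s}) precedes start ({self.start_s})")


@dataclass(frozen=True)
class SequenceMetrics:
    whale_id: str
    sequence_id: str
    breath_count: int
    sequence_duration_s: float
    total_inhalation_s: float
    mean_ibi_s: float | None
    accumulation_rate: float | None
    initial_inhalation_s: float
    terminal_inhalation_s: float | None


def inhalation_duration(breath: BreathEvent | tuple[float, float]) -> float:
    """Inhalation duration of one breath: half the blow's visible duration."""
    if isinstance(breath, BreathEvent):
        start, end = breath.start_s, breath.end_s
    else:
        start, end = breath
    if end < start:
        raise ValidationError(f"breath end ({end}) precedes start ({start})")
    return (end - start) / 2.0


def classify_breaths(n: int) -> list[str]:
    """Breath classes for an ``n``-breath sequence.

    The first breath is ``initial``, the last ``terminal``, any in between
    ``middle``; a single-breath sequence is classified ``initial`` only.
    """
    if n < 1:
        raise ValidationError("sequence must contain at least one breath")
    if n == 1:
        return ["initial"]
    return ["initial"] + ["middle"] * (n - 2) + ["terminal"]


def _check_ordered(starts: np.ndarray, ends: np.ndarray) -> None:
    if np.any(ends < starts):
        raise ValidationError("breath end precedes start")
    if np.any(starts[1:] < ends[:-1]):
        raise ValidationError("breaths are unordered or overlapping")


def summarize_sequence(breaths: list[BreathEvent] | pd.DataFrame) -> SequenceMetrics:
    """Compute all sequence-level respiration metrics for one sequence."""
    if isinstance(breaths, pd.DataFrame):
        df = breaths.sort_values("start_s")
        whale_id = str(df["whale_id"].iloc[0])
        sequence_id = str(df["sequence_id"].iloc[0])
        starts = df["start_s"].to_numpy(float)
        ends = df["end_s"].to_numpy(float)
    else:
        if not breaths:
            raise ValidationError("sequence must contain at least one breath")
        whale_id = breaths[0].whale_id
        sequence_id = breaths[0].sequence_id
        starts = np.array([b.start_s for b in breaths], float)
        ends = np.array([b.end_s for b in breaths], float)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
    if starts.size == 0:
        raise ValidationError("sequence must contain at least one breath")
    _check_ordered(starts, ends)

    inh = (ends - starts) / 2.0
    n = starts.size
    total = float(inh.sum())
    duration = float(starts[-1] - starts[0])

    if n >= 2:
        gaps = starts[1:] - ends[:-1]
        mean_ibi = float(gaps.mean())
        x = starts - starts[0]
        y = np.cumsum(inh)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = float(xc @ (y - y.mean()) / sxx) if sxx > 0 else None
        terminal = float(inh[-1])
    else:
        mean_ibi = None
        slope = None
        terminal = None

    return SequenceMetrics(
        whale_id=whale_id,
        sequence_id=sequence_id,
        breath_count=int(n),
        sequence_duration_s=duration,
        total_inhalation_s=total,
        mean_ibi_s=mean_ibi,
        accumulation_rate=slope,
        initial_inhalation_s=float(inh[0]),
        terminal_inhalation_s=terminal,
    )


def sequence_table(events: pd.DataFrame, dives: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sequence metrics table from a breath-event table.

    When a dive table is supplied, each sequence is matched to its preceding
    dive (latest dive ending at or before the first breath) and following
    dive (earliest dive starting at or after the last breath), and the dive's
    duration, tactic, and bubble-blast flag are attached with
    ``preceding_`` / ``following_`` prefixes.
    """
    rows = []
    for (whale_id, seq_id), grp in events.groupby(
            ["whale_id", "sequence_id"], sort=True):
        m = summarize_sequence(grp)
        rows.append({
            "whale_id": m.whale_id,
            "sequence_id": m.sequence_id,
            "breath_count": m.breath_count,
            "sequence_duration_s": m.sequence_duration_s,
            "total_inhalation_s": m.total_inhalation_s,
            "mean_ibi_s": m.mean_ibi_s,
            "accumulation_rate": m.accumulation_rate,
            "initial_inhalation_s": m.initial_inhalation_s,
            "terminal_inhalation_s": m.terminal_inhalation_s,
            "first_breath_start_s": float(grp["start_s"].min()),
            "last_breath_end_s": float(grp["end_s"].max()),
        })
    table = pd.DataFrame(rows)
    if dives is None or table.empty:
        return table

    for prefix in ("preceding", "following"):
        for col in ("dive_id", "tactic", "bubble_blast", "dive_duration_s"):
            table[f"{prefix}_{col}"] = pd.NA
    dives = dives.sort_values("start_s")
    for i, row in table.iterrows():
        cand = dives[(dives["whale_id"] == row["whale_id"])
                     & (dives["end_s"] <= row["first_breath_start_s"] + 1e-9)]
        if len(cand):
            d = cand.iloc[-1]
            table.loc[i, ["preceding_dive_id", "preceding_tactic",
                          "preceding_bubble_blast",
                          "preceding_dive_duration_s"]] = [
                d["dive_id"], d["tactic"], bool(d["bubble_blast"]),
                float(d["end_s"] - d["start_s"])]
        cand = dives[(dives["whale_id"] == row["whale_id"])
                     & (dives["start_s"] >= row["last_breath_end_s"] - 1e-9)]
        if len(cand):
            d = cand.iloc[0]
            table.loc[i, ["following_dive_id", "following_tactic",
                          "following_bubble_blast",
                          "following_dive_duration_s"]] = [
                d["dive_id"], d["tactic"], bool(d["bubble_blast"]),
                float(d["end_s"] - d["start_s"])]
    return table


def travel_respiration_rate(breath_count: int, travel_duration_s: float) -> float:
    """Breaths per minute over a travel observation period."""
    if travel_duration_s <= 0:
        raise ValidationError("travel duration must be positive")
    if breath_count < 0:
        raise ValidationError("breath count must be non-negative")
    return 60.0 * breath_count / travel_duration_s


def _haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def mean_swim_speed(fixes: pd.DataFrame) -> float:
    """Mean swim speed (m/s) from an ordered GPS fix table.

    Great-circle distances between consecutive fixes are summed and divided
    by the total elapsed time of the observation.
    """
    if len(fixes) < 2:
        raise ValidationError("at least two GPS fixes are required")
    fixes = fixes.sort_values("time_s")
    t = fixes["time_s"].to_numpy(float)
    lat = fixes["lat"].to_numpy(float)
    lon = fixes["lon"].to_numpy(float)
    elapsed = t[-1] - t[0]
    if elapsed <= 0:
        raise ValidationError("GPS fixes span zero time")
    dist = _haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum()
    return float(dist / elapsed)


def match_bai(observation_date, bai_series: pd.DataFrame,
              window_days: int = 14):
    """Nearest dated BAI estimate within ``window_days`` of an observation.

    A same-day measurement is preferred; otherwise the nearest within the
    window, with ties broken toward the earlier date.  Returns the matching
    row (as a Series) or ``None`` when nothing falls inside the window.
    """
    if bai_series.empty:
        return None
    obs = pd.Timestamp(observation_date)
    dates = pd.to_datetime(bai_series["date"])
    delta_days = (dates - obs).dt.total_seconds().to_numpy() / 86400.0
    absd = np.abs(delta_days)
    inside = absd <= window_days
    if not inside.any():
        return None
    # ties at +/- k days resolve to the earlier measurement
    key = absd + np.where(delta_days > 0, 1e-9, 0.0)
    key[~inside] = np.inf
    return bai_series.iloc[int(np.argmin(key))]


def standardized_nares_area(area_m2: float, tl_m: float,
                            exponent: float = 1.0) -> float:
    """Naris area standardized by total length (``area / TL**exponent``).

    The default divides by TL once; dividing by TL**2 (an area-for-area
    standardization) is available through ``exponent``.
    """
    if tl_m <= 0:
        raise ValidationError("total length must be positive")
    if area_m2 < 0:
        raise ValidationError("naris area must be non-negative")
    return area_m2 / tl_m ** exponent
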