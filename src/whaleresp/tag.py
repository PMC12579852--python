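"""Dive and breath detection from tag depth time series.

A biologging tag records depth (m, positive down) at a fixed sampling rate.
Dives are maximal runs of samples at or below a depth threshold; surface
periods lie between consecutive dives.  Within a surface period, each
surfacing (run shallower than the threshold) bounded by very shallow dips is
taken as one breath; a surfacing longer than a cutoff (default 10 s) is
counted as two breaths, so the per-period count is a *minimum* estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "DepthSeries",
    "BreathCountResult",
    "find_dives",
    "count_breaths",
    "group_travel_series",
    "tag_travel_respiration_rate",
    "moving_median",
]


@dataclass
class DepthSeries:
    """Uniformly sampled depth record (m, positive down)."""

    sampling_rate_hz: float
    depth_m: np.ndarray
    start_s: float = 0.0

    def __post_init__(self):
        self.depth_m = np.asarray(self.depth_m, float)
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.depth_m.ndim != 1:
            raise ValidationError("depth must be one-dimensional")
        if self.depth_m.size and np.nanmin(self.depth_m) < 0:
            raise ValidationError("depth must be non-negative (positive down)")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.depth_m.size) / self.sampling_rate_hz

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DepthSeries":
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValidationError("depth series needs at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("depth series must be uniformly sampled")
        return cls(sampling_rate_hz=1.0 / dt[0],
                   depth_m=df["depth_m"].to_numpy(float), start_s=t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "depth_m": self.depth_m})


@dataclass
class BreathCountResult:
    """Minimum breath count for one surface period."""

    count: int
    surfacing_times_s: list[float] = field(default_factory=list)
    long_surfacings_s: list[float] = field(default_factory=list)


def moving_median(series: DepthSeries, width: int) -> DepthSeries:
    """Optional moving-median smoother for noisy depth records (off by default)."""
    if width < 1 or width % 2 == 0:
        raise ValidationError("width must be a positive odd integer")
    if width == 1:
        return series
    d = pd.Series(series.depth_m).rolling(width, center=True, min_periods=1)
    return DepthSeries(series.sampling_rate_hz,
                       d.median().to_numpy(), series.start_s)


def _runs(mask: np.ndarray):
    """(start_idx, stop_idx) pairs of maximal True runs; stop is exclusive."""
    if mask.size == 0:
        return []
    padded = np.r_[False, mask, False]
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def find_dives(series: DepthSeries, threshold_m: float = 0.2,
               min_duration_s: float = 5.0) -> pd.DataFrame:
    """Detect dives as maximal runs with depth >= threshold.

    A sample is submerged when ``depth >= threshold``; a run of ``k``
    submerged samples represents ``k / fs`` seconds, and runs shorter than
    ``min_duration_s`` are discarded.  Returns a frame with ``start_s``,
    ``end_s``, ``duration_s``, and ``max_depth_m``.
    """
    if threshold_m <= 0:
        raise ValidationError("threshold must be positive")
    if series.depth_m.size == 0:
        raise ValidationError("empty depth series")
    fs = series.sampling_rate_hz
    rows = []
    for i0, i1 in _runs(series.depth_m >= threshold_m):
        duration = (i1 - i0) / fs
        if duration >= min_duration_s:
            start = series.start_s + i0 / fs
            rows.append({
                "start_s": start,
                "end_s": start + duration,
                "duration_s": duration,
                "max_depth_m": float(series.depth_m[i0:i1].max()),
            })
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s",
                                       "max_depth_m"])


def count_breaths(series: DepthSeries, period_start_s: float,
                  period_end_s: float, threshold_m: float = 0.2,
                  two_breath_cutoff_s: float = 10.0) -> BreathCountResult:
    """Minimum breath count within one surface period.

    Each surfacing (run with depth < threshold) counts one breath; any
    surfacing longer than the cutoff counts exactly two (it must contain at
    least two breaths) and is additionally reported in
    ``long_surfacings_s`` because the true number could be higher.
    """
    fs = series.sampling_rate_hz
    t = series.times_s
    sel = (t >= period_start_s - 1e-9) & (t < period_end_s - 1e-9)
    depth = series.depth_m[sel]
    tsel = t[sel]
    count = 0
    surfacings, long_flags = [], []
    for i0, i1 in _runs(depth < threshold_m):
        duration = (i1 - i0) / fs
        surfacings.append(float(tsel[i0]))
        if duration > two_breath_cutoff_s:
            count += 2
            long_flags.append(duration)
        else:
            count += 1
    return BreathCountResult(count=count, surfacing_times_s=surfacings,
                             long_surfacings_s=long_flags)


def group_travel_series(dives: pd.DataFrame) -> pd.Series:
    """Assign consecutive travel dives to travel-series ids.

    Maximal runs of ``behavior == "travel"`` share one 1-based series id;
    any non-travel dive breaks the run and itself receives no id (NA).
    """
    if not dives["start_s"].is_monotonic_increasing:
        raise ValidationError("dives must be time-ordered")
    is_travel = (dives["behavior"] == "travel").to_numpy()
    ids = np.full(len(dives), 0)
    series_id = 0
    prev = False
    for i, trav in enumerate(is_travel):
        if trav:
            if not prev:
                series_id += 1
            ids[i] = series_id
        prev = trav
    out = pd.Series(ids, index=dives.index, dtype="Int64")
    return out.mask(out == 0)


def tag_travel_respiration_rate(min_breath_counts, series_durations_s) -> float:
    """Pooled travel respiration rate (breaths/min) over travel series."""
    counts = np.asarray(list(min_breath_counts), float)
    durations = np.asarray(list(series_durations_s), float)
    if counts.size != durations.size:
        raise ValidationError("counts and durations must align")
    total_time = durations.sum()
    if counts.size == 0:
        return 0.0
    if total_time <= 0:
        raise ValidationError("total travel series time must be positive")
    return float(60.0 * counts.sum() / total_time)
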