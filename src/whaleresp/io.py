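"""Table schemas, validation, and CSV round-trips for the pipeline.

Every table that moves between pipeline stages has a declared schema
(required/optional columns with dtypes and simple invariants).  All CSVs are
UTF-8, comma-separated with a header row, ``.`` decimal, ISO-8601 dates, and
times as float seconds from an arbitrary epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TableSchema",
    "ValidationError",
    "SCHEMAS",
    "validate_table",
    "read_table",
    "write_table",
]


class ValidationError(ValueError):
    """Raised when an input table or argument violates its contract."""


@dataclass(frozen=True)
class TableSchema:
    """Declared structure of one pipeline table.

    ``required`` maps column name -> dtype kind ("float", "int", "str",
    "bool", "date").  ``checks`` is a list of (description, callable) row-set
    invariants evaluated on the typed frame; each callable returns a boolean
    mask of *bad* rows.
    """

    name: str
    required: dict[str, str]
    optional: dict[str, str] = field(default_factory=dict)
    checks: tuple = ()


def _nonneg(col):
    return lambda df: df[col] < 0


def _end_before_start(start, end):
    return lambda df: df[end] < df[start]


SCHEMAS: dict[str, TableSchema] = {
    "breath_events": TableSchema(
        name="breath_events",
        required={
            "whale_id": "str",
            "sequence_id": "str",
            "start_s": "float",
            "end_s": "float",
        },
        optional={"breath_class": "str", "naris_area_m2": "float"},
        checks=(
            ("end_s < start_s", _end_before_start("start_s", "end_s")),
            ("negative start_s", _nonneg("start_s")),
        ),
    ),
    "dives": TableSchema(
        name="dives",
        required={
            "whale_id": "str",
            "dive_id": "str",
            "start_s": "float",
            "end_s": "float",
            "behavior": "str",
            "tactic": "str",
            "bubble_blast": "bool",
        },
        optional={"max_depth_m": "float"},
        checks=(
            ("end_s <= start_s (non-positive duration)",
             lambda df: df["end_s"] <= df["start_s"]),
        ),
    ),
    "depth_series": TableSchema(
        name="depth_series",
        required={"time_s": "float", "depth_m": "float"},
        checks=(
            ("negative depth", _nonneg("depth_m")),
            ("non-monotone time", lambda df: pd.Series(
                np.r_[False, np.diff(df["time_s"].to_numpy()) <= 0],
                index=df.index)),
        ),
    ),
    "morph_tl": TableSchema(
        name="morph_tl",
        required={"whale_id": "str", "year": "int",
                  "tl_mean_m": "float", "tl_sd_m": "float"},
        checks=(("negative tl_sd_m", _nonneg("tl_sd_m")),),
    ),
    "morph_bai": TableSchema(
        name="morph_bai",
        required={"whale_id": "str", "date": "date",
                  "bai_mean": "float", "bai_sd": "float"},
        checks=(("negative bai_sd", _nonneg("bai_sd")),),
    ),
    "gps_fixes": TableSchema(
        name="gps_fixes",
        required={"time_s": "float", "lat": "float", "lon": "float"},
    ),
    "sequence_metrics": TableSchema(
        name="sequence_metrics",
        required={
            "whale_id": "str",
            "sequence_id": "str",
            "breath_count": "int",
            "sequence_duration_s": "float",
            "total_inhalation_s": "float",
        },
        optional={
            "mean_ibi_s": "float",
            "accumulation_rate": "float",
            "initial_inhalation_s": "float",
            "terminal_inhalation_s": "float",
            "preceding_dive_id": "str",
            "following_dive_id": "str",
        },
    ),
    "travel_observations": TableSchema(
        name="travel_observations",
        required={
            "whale_id": "str",
            "observation_id": "str",
            "breath_count": "int",
            "travel_duration_s": "float",
            "swim_speed_ms": "float",
        },
    ),
}

_DTYPES = {"float": float, "int": "int64", "str": str, "bool": bool}


def _coerce(series: pd.Series, kind: str, name: str, errors: list[str]):
    try:
        if kind == "date":
            return pd.to_datetime(series, format="ISO8601")
        if kind == "bool":
            if series.dtype == object:
                mapped = series.map(
                    {"True": True, "False": False, True: True, False: False,
                     1: True, 0: False, "1": True, "0": False})
                if mapped.isna().any():
                    raise ValueError("unparseable boolean")
                return mapped.astype(bool)
            return series.astype(bool)
        return series.astype(_DTYPES[kind])
    except (ValueError, TypeError) as exc:
        errors.append(f"column {name!r}: cannot coerce to {kind} ({exc})")
        return series


def validate_table(table, schema: TableSchema | str) -> pd.DataFrame:
    """Validate ``table`` (a DataFrame or a CSV path) against a schema.

    Returns the typed DataFrame; raises :class:`ValidationError` with a
    message naming every missing column, bad dtype, and first offending row
    of each invariant otherwise.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    df = table.copy()
    errors: list[str] = []
    for col in schema.required:
        if col not in df.columns:
            errors.append(f"missing required column {col!r}")
    if errors:
        raise ValidationError(
            f"table {schema.name!r}: " + "; ".join(errors))
    for col, kind in schema.required.items():
        df[col] = _coerce(df[col], kind, col, errors)
    for col, kind in schema.optional.items():
        if col in df.columns and df[col].notna().any():
            df[col] = _coerce(df[col], kind, col, errors)
    if not errors:
        for desc, check in schema.checks:
            bad = check(df)
            if bool(np.asarray(bad).any()):
                rows = list(df.index[np.asarray(bad)][:5])
                errors.append(f"invariant violated ({desc}) at rows {rows}")
    if errors:
        raise ValidationError(
            f"table {schema.name!r}: " + "; ".join(errors))
    return df


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    return validate_table(path, schema)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
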