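"""Readers and writers for raw biologger streams and pipeline tables.

GPS loggers sample position at a nominal 5 Hz and accelerometers record the
dorsal z-axis at a nominal 100 Hz.  Both arrive as per-bird CSV files; this
module normalises them into time-sorted pandas DataFrames carrying stream
metadata in ``DataFrame.attrs``.  The tidy per-second track table produced at
the end of the pipeline round-trips through :func:`write_track_table` /
:func:`read_track_table` without numeric loss beyond 1e-9.

CSV dialect: comma-separated, UTF-8, header row required, missing values as
empty cells.  Timestamps are either numeric seconds-since-epoch or ISO-8601
strings; everything is treated as UTC and no timezone arithmetic is done
anywhere downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyStreamError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Stable column order of the per-second track table.
TRACK_COLUMNS = [
    "bird_id", "loft_id", "flight_date", "t", "flight_time", "iteration",
    "x", "y", "speed", "flap_frequency", "habitat", "group_size",
    "absolute_spread", "distance_to_centroid", "front_back", "left_right",
    "position",
]

_TRACK_NUMERIC = [
    "t", "flight_time", "iteration", "x", "y", "speed", "flap_frequency",
    "group_size", "absolute_spread", "distance_to_centroid", "front_back",
    "left_right",
]


@dataclass(frozen=True)
class GpsFix:
    """One GPS position record (nominal 0.2 s cadence)."""

    bird_id: str
    loft_id: str
    flight_date: str
    t: float
    lon: float
    lat: float


@dataclass(frozen=True)
class AccelSample:
    """One z-axis accelerometer reading in gravitational units (nominal 0.01 s cadence)."""

    bird_id: str
    flight_date: str
    t: float
    z: float


def _parse_time(col: pd.Series) -> pd.Series:
    """Coerce a timestamp column to float seconds since epoch (UTC)."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.astype(float)
    try:
        parsed = pd.to_datetime(col, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamp column: {exc}") from exc
    return parsed.astype("int64") / 1e9


def read_gps(path, bird_id: str, loft_id: str, flight_date: str) -> pd.DataFrame:
    """Read one bird's GPS log.

    Returns a DataFrame with columns ``t, lon, lat`` sorted by ``t`` with
    duplicate timestamps collapsed to the first occurrence (count logged).
    Stream identity is kept in ``attrs`` (``bird_id``, ``loft_id``,
    ``flight_date``).
    """
    df = _read_csv(path, required={"timestamp", "lon", "lat"})
    df = df.rename(columns={"timestamp": "t"})
    df["t"] = _parse_time(df["t"])
    for c in ("lon", "lat"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        if df[c].isna().any():
            raise FormatError(f"non-numeric values in column {c!r} of {path}")
    if (df["lat"].abs() > 90).any():
        raise ValidationError(f"latitude outside [-90, 90] in {path}")
    if (df["lon"].abs() > 180).any():
        raise ValidationError(f"longitude outside [-180, 180] in {path}")

    df = df.sort_values("t", kind="mergesort").reset_index(drop=True)
    before = len(df)
    df = df.drop_duplicates(subset="t", keep="first").reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("read_gps %s: dropped %d duplicate-timestamp rows", path, dropped)
    df = df[["t", "lon", "lat"]]
    df.attrs.update(bird_id=bird_id, loft_id=loft_id, flight_date=flight_date,
                    dropped_duplicates=dropped)
    return df


def read_accel(path, bird_id: str, flight_date: str) -> pd.DataFrame:
    """Read one bird's z-axis accelerometry log.

    Returns a DataFrame with columns ``t, z`` sorted by ``t``; the median
    inter-sample gap is inverted into a sampling-rate estimate stored in
    ``attrs['sample_rate_hz']``.
    """
    df = _read_csv(path, required={"timestamp", "z"})
    df = df.rename(columns={"timestamp": "t"})
    df["t"] = _parse_time(df["t"])
    df["z"] = pd.to_numeric(df["z"], errors="coerce")
    if df["z"].isna().any():
        raise FormatError(f"non-numeric z values in {path}")
    if not df["t"].is_monotonic_increasing:
        logger.warning("read_accel %s: rows out of order, sorting", path)
        df = df.sort_values("t", kind="mergesort").reset_index(drop=True)
    df = df.drop_duplicates(subset="t", keep="first").reset_index(drop=True)
    gaps = np.diff(df["t"].to_numpy())
    rate = float(1.0 / np.median(gaps)) if len(gaps) else float("nan")
    df = df[["t", "z"]]
    df.attrs.update(bird_id=bird_id, flight_date=flight_date, sample_rate_hz=rate)
    return df


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyStreamError(f"{path} is empty") from exc
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path} missing required columns: {sorted(missing)}")
    if len(df) == 0:
        raise EmptyStreamError(f"{path} contains a header but no data rows")
    return df


def write_track_table(records: pd.DataFrame, path) -> None:
    """Write per-second track records as CSV with a stable column order.

    Missing values become empty cells.  Numeric fields survive a round trip
    through :func:`read_track_table` to within 1e-9.
    """
    df = records.copy()
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[TRACK_COLUMNS]
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_track_table(path) -> pd.DataFrame:
    """Read a track table written by :func:`write_track_table`."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path} missing track columns: {sorted(missing)}")
    for col in _TRACK_NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[TRACK_COLUMNS]
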