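"""Per-second aggregation, stream merging and autocorrelation subsampling.

The GPS stream (5 Hz) and the flap-frequency stream (one estimate per
15-sample accelerometry window) live on different clocks; both are reduced to
per-second medians and merged on (bird, flight, second).  Merged records are
then subsampled at a rate of 15 per-second rows per bird and flight to
attenuate temporal autocorrelation, on a second-grid shared by all of a
flock's birds so that timestamps still match across flock members.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _acf

from .errors import DegenerateInputError, IntegrityError

logger = logging.getLogger(__name__)

DEFAULT_SUBSAMPLE_RATE = 15

#: merge keys identifying one bird-second of one flight
KEYS = ["bird_id", "loft_id", "flight_date", "t"]


def to_per_second(stream: pd.DataFrame, value_cols,
                  t_col: str = "t") -> pd.DataFrame:
    """Median of each value column per whole second (floor of ``t_col``).

    Seconds with no rows are absent; medians ignore missing values
    componentwise.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    if len(stream) == 0:
        return pd.DataFrame({t_col: pd.Series(dtype=float),
                             **{c: pd.Series(dtype=float) for c in value_cols}})
    sec = np.floor(stream[t_col].to_numpy(dtype=float))
    out = (stream.assign(**{t_col: sec})
           .groupby(t_col, as_index=False)[list(value_cols)]
           .median())
    return out


def merge_streams(gps_per_s: pd.DataFrame,
                  flap_per_s: pd.DataFrame | None = None,
                  habitat_per_s: pd.DataFrame | None = None,
                  flock_per_s: pd.DataFrame | None = None) -> pd.DataFrame:
    """Left-join the per-second streams onto the position-bearing records.

    A record exists only where GPS exists; flap and flock fields are missing
    where their stream has no matching second, and unmatched seconds of the
    secondary streams are dropped (counts logged).  Duplicate keys in any
    stream raise :class:`~flocktrace.errors.IntegrityError`.
    """
    merged = gps_per_s.copy()
    _check_keys(merged, "gps")
    for name, other in (("flap", flap_per_s), ("habitat", habitat_per_s),
                        ("flock", flock_per_s)):
        if other is None or len(other) == 0:
            continue
        keys = [k for k in KEYS if k in other.columns]
        _check_keys(other, name, keys)
        before = len(merged)
        merged = merged.merge(other, how="left", on=keys)
        if len(merged) != before:
            raise IntegrityError(f"{name} stream duplicated rows on merge")
        unmatched = len(other) - len(other.merge(gps_per_s[keys], on=keys))
        if unmatched:
            logger.info("merge_streams: %d %s seconds had no GPS second and "
                        "were dropped", unmatched, name)
    if len(merged) == 0:
        logger.warning("merge_streams: no overlapping records")
    return merged


def _check_keys(df: pd.DataFrame, name: str, keys=None) -> None:
    keys = keys or [k for k in KEYS if k in df.columns]
    if keys and df.duplicated(subset=keys).any():
        raise IntegrityError(f"conflicting duplicate keys in {name} stream")


def subsample(records: pd.DataFrame,
              rate: int = DEFAULT_SUBSAMPLE_RATE) -> pd.DataFrame:
    """Retain every ``rate``-th per-second row per bird and flight.

    The retained seconds lie on a per-flight grid anchored at the flight's
    first retained second and shared by all of the flock's birds, so
    timestamps match across flock members; for a gap-free stream starting at
    the anchor this retains ordinal positions 0, rate, 2*rate, ... —
    ceil(n/rate) rows.  ``rate=1`` is the identity, so subsampling is
    idempotent.
    """
    if rate < 1:
        raise ValueError("rate must be >= 1")
    if len(records) == 0 or rate == 1:
        return records.copy()
    anchor = records.groupby(["loft_id", "flight_date"])["t"].transform("min")
    keep = ((records["t"] - anchor) % rate) == 0
    return records.loc[keep].reset_index(drop=True)


def autocorrelation(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 1..max_lag, missing values dropped.

    Raises on zero-variance input (autocorrelation undefined).
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) <= max_lag + 2:
        raise DegenerateInputError("series too short for requested max_lag")
    if np.var(x) == 0:
        raise DegenerateInputError("constant series has undefined autocorrelation")
    return _acf(x, nlags=max_lag, fft=True)[1:]
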