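"""Calendar-date <-> real-valued-age helpers.

All age and duration arithmetic in the package goes through these helpers so
that a single year-length convention (the mean Gregorian year of 365.2425
days) is used everywhere.  Dates are handled as numpy ``datetime64[D]`` /
pandas Timestamps; ages and durations are floats in years.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

#: days per year (mean Gregorian year)
DAYS_PER_YEAR = 365.2425

DateLike = "str | _dt.date | pd.Timestamp | np.datetime64"


def as_date(value) -> pd.Timestamp:
    """Coerce an ISO-8601 string / date / Timestamp to a normalized Timestamp."""
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        raise ValueError(f"not a date: {value!r}")
    return ts.normalize()


def years_between(start, end) -> float:
    """Signed duration from *start* to *end* in (fractional) years."""
    d0 = pd.Timestamp(start)
    d1 = pd.Timestamp(end)
    return (d1 - d0).days / DAYS_PER_YEAR


def years_between_vec(start, end) -> np.ndarray:
    """Vectorized :func:`years_between` for datetime64 arrays/Series."""
    start = pd.to_datetime(start)
    end = pd.to_datetime(end)
    delta = np.asarray(end, dtype="datetime64[D]") - np.asarray(start, dtype="datetime64[D]")
    return delta.astype(float) / DAYS_PER_YEAR


def add_years(date, years: float) -> pd.Timestamp:
    """Date shifted by a (fractional) number of years, rounded to whole days."""
    return pd.Timestamp(date) + pd.Timedelta(days=round(years * DAYS_PER_YEAR))


def add_years_vec(dates, years) -> pd.DatetimeIndex:
    dates = pd.to_datetime(dates)
    offsets = np.round(np.asarray(years, dtype=float) * DAYS_PER_YEAR).astype("timedelta64[D]")
    return pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[D]") + offsets)
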