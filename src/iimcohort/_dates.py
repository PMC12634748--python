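"""Calendar-date helpers.

All window arithmetic in the pipeline is month-denominated and day-granular:
``date + k months`` lands on the same day-of-month k months later, clamped to
the last day of the target month (Aug 31 + 6 months -> Feb 28/29).  Windows
are half-open [start, end) unless a contract says otherwise.
"""

from __future__ import annotations

import pandas as pd

DAYS_PER_YEAR = 365.25


def to_date(x) -> pd.Timestamp:
    """Coerce to a midnight-normalized Timestamp."""
    ts = pd.Timestamp(x)
    if ts is pd.NaT:
        raise ValueError("not a date")
    return ts.normalize()


def add_months(d, months: int) -> pd.Timestamp:
    """Clamped calendar-month shift (works for negative ``months`` too)."""
    return pd.Timestamp(d) + pd.DateOffset(months=months)


def completed_years(birth, on) -> int:
    """Age in completed years (floor) on a given date.

    A Feb-29 birthday is treated as completed on Mar 1 of non-leap years.
    """
    b, o = pd.Timestamp(birth), pd.Timestamp(on)
    years = o.year - b.year
    if (o.month, o.day) < (b.month, b.day):
        years -= 1
    return years


def days_between(start, end) -> int:
    return (pd.Timestamp(end) - pd.Timestamp(start)).days
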