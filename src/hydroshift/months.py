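"""Month-key helpers.

Throughout the package a month is identified by a ``"YYYY-MM"`` string.
String keys survive CSV round trips unchanged and sort chronologically,
which keeps joins across tables and grids trivial.
"""

from __future__ import annotations

import calendar

import pandas as pd


def month_range(start: str, end: str) -> list[str]:
    """Inclusive list of month keys from ``start`` to ``end``."""
    periods = pd.period_range(start=start, end=end, freq="M")
    if len(periods) == 0:
        raise ValueError(f"empty month range {start}..{end}")
    return [str(p) for p in periods]


def month_year(month: str) -> int:
    return int(month[:4])


def month_cal(month: str) -> int:
    """Calendar month 1..12."""
    return int(month[5:7])


def days_in_month(month: str) -> int:
    return calendar.monthrange(month_year(month), month_cal(month))[1]


def add_months(month: str, k: int) -> str:
    return str(pd.Period(month, freq="M") + k)
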