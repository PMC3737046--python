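"""Fiscal-quarter arithmetic for claims series.

The provincial reporting year starts April 1, so October–December of
calendar year Y is labelled "YQ3" (e.g. October 2000 falls in 2000Q3)
and January–March of Y+1 is "YQ4".  A calendar scheme (Q1 = Jan–Mar)
is available for reuse on other data.
"""
from __future__ import annotations

import datetime as dt
from typing import Iterable

import pandas as pd

__all__ = [
    "quarter_label",
    "quarter_start",
    "quarter_bounds",
    "quarter_range",
    "quarter_index",
]


def quarter_label(date, scheme: str = "fiscal") -> str:
    """Label the quarter containing ``date``, e.g. '2000Q3'."""
    ts = pd.Timestamp(date)
    if scheme == "fiscal":
        fy = ts.year if ts.month >= 4 else ts.year - 1
        q = (ts.month - 4) % 12 // 3 + 1
    elif scheme == "calendar":
        fy = ts.year
        q = (ts.month - 1) // 3 + 1
    else:
        raise ValueError(f"unknown quarter scheme: {scheme!r}")
    return f"{fy}Q{q}"


def quarter_start(label: str, scheme: str = "fiscal") -> dt.date:
    """First calendar day of a labelled quarter."""
    year, q = label.split("Q")
    year, q = int(year), int(q)
    if not 1 <= q <= 4:
        raise ValueError(f"bad quarter label: {label!r}")
    if scheme == "fiscal":
        month = 4 + (q - 1) * 3
        if month > 12:
            month -= 12
            year += 1
    elif scheme == "calendar":
        month = 1 + (q - 1) * 3
    else:
        raise ValueError(f"unknown quarter scheme: {scheme!r}")
    return dt.date(year, month, 1)


def quarter_bounds(label: str, scheme: str = "fiscal") -> tuple[dt.date, dt.date]:
    """Inclusive (first day, last day) of a labelled quarter."""
    start = quarter_start(label, scheme)
    end = (pd.Timestamp(start) + pd.DateOffset(months=3) - pd.Timedelta(days=1)).date()
    return start, end


def quarter_range(start, end, scheme: str = "fiscal") -> list[str]:
    """Ordered labels of every quarter touching [start, end]."""
    labels = []
    cur = pd.Timestamp(quarter_start(quarter_label(start, scheme), scheme))
    stop = pd.Timestamp(end)
    while cur <= stop:
        labels.append(quarter_label(cur, scheme))
        cur += pd.DateOffset(months=3)
    return labels


def quarter_index(labels: Iterable[str], origin: str) -> dict[str, int]:
    """Map labels to 1-based indices counting from the origin quarter."""
    oy, oq = origin.split("Q")
    base = int(oy) * 4 + int(oq)
    return {lab: int(lab.split("Q")[0]) * 4 + int(lab.split("Q")[1]) - base + 1
            for lab in labels}
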