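"""Longitudinal atrophy rates: per-subject linear least-squares slopes.

Each subject's indicator values over follow-up visits are fit with ordinary
least squares against visit time in years; the slope is the annual changing
rate of the indicator.  Subjects need at least three visits spanning at least
one year to yield a usable rate (shorter follow-up gives slopes dominated by
measurement noise).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

MIN_VISITS = 3
MIN_FOLLOW_UP_YEARS = 1.0


@dataclasses.dataclass
class RateRecord:
    subject_id: str
    group: str
    gmv_rate: float
    thickness_rate: float
    n_visits: int
    follow_up_years: float


def llse_rate(times, values) -> tuple[float, float]:
    """OLS slope and intercept of indicator values against time (years).

    slope b = sum((t - tbar)(y - ybar)) / sum((t - tbar)^2), in indicator
    units per year.  Requires >= 3 points and non-degenerate times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1D sequences")
    if len(t) < MIN_VISITS:
        raise ValueError(f"need >= {MIN_VISITS} visits, got {len(t)}")
    if np.ptp(t) == 0:
        raise ValueError("all visit times identical; slope undefined")
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def estimate_rates(
    indicator_table: pd.DataFrame,
    value_columns: tuple[str, str] = ("gmv_voi", "thickness_voi"),
    enforce_follow_up: bool = True,
) -> pd.DataFrame:
    """Per-subject annual rates for both indicators.

    ``indicator_table`` holds one row per subject-visit with ``subject_id``,
    ``group``, ``visit_time_years`` and the indicator columns.  Subjects with
    fewer than 3 visits (or, when ``enforce_follow_up``, under 1 year of
    follow-up) are dropped with a note in the result's ``attrs['excluded']``.
    """
    records = []
    excluded = []
    for sid, sub in indicator_table.groupby("subject_id", sort=False):
        t = sub["visit_time_years"].to_numpy(dtype=float)
        span = float(np.ptp(t))
        if len(t) < MIN_VISITS or (enforce_follow_up and span < MIN_FOLLOW_UP_YEARS):
            excluded.append(sid)
            continue
        rates = {}
        for col in value_columns:
            rates[col], _ = llse_rate(t, sub[col].to_numpy(dtype=float))
        records.append(
            RateRecord(
                subject_id=sid,
                group=str(sub["group"].iloc[0]),
                gmv_rate=rates[value_columns[0]],
                thickness_rate=rates[value_columns[1]],
                n_visits=len(t),
                follow_up_years=span,
            )
        )
    out = pd.DataFrame([dataclasses.asdict(r) for r in records])
    out.attrs["excluded"] = excluded
    return out
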