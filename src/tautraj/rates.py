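"""Annualized rate-of-change estimation for ROI tau SUVR and PACC series.

The annualized rate for a subject/measure is the two-point difference
divided by the time interval when exactly two observations exist, and the
ordinary least-squares slope of value on time (intercept included) for
three or more observations; the two rules coincide exactly at n = 2.
Units are SUVR/year for tau ROIs and PACC points/year for cognition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["annualized_rate", "build_rate_table"]


def annualized_rate(times, values) -> float:
    """Annualized rate from one longitudinal series.

    ``times`` are years from baseline, strictly increasing; two points give
    (v2 - v1)/(t2 - t1), three or more the OLS slope.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-d arrays")
    if len(t) < 2:
        raise ValueError("need at least 2 timepoints for a rate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(t) == 2:
        return float((v[1] - v[0]) / (t[1] - t[0]))
    tc = t - t.mean()
    return float((tc @ (v - v.mean())) / (tc @ tc))


def build_rate_table(series: pd.DataFrame) -> pd.DataFrame:
    """One annualized rate per (subject, measure) from a long series table.

    Returns columns ``subject_id, measure, rate, n_timepoints, span_yr``.
    Series with a single timepoint are omitted (they carry no rate);
    duplicate (subject, measure, time) rows are rejected upstream by the
    series validator.
    """
    rows = []
    for (sid, measure), grp in series.groupby(["subject_id", "measure"], sort=False):
        t = grp["time_yr"].to_numpy(float)
        v = grp["value"].to_numpy(float)
        order = np.argsort(t)
        t, v = t[order], v[order]
        if len(t) < 2:
            continue
        rows.append({
            "subject_id": sid,
            "measure": measure,
            "rate": annualized_rate(t, v),
            "n_timepoints": len(t),
            "span_yr": float(t[-1] - t[0]),
        })
    return pd.DataFrame(rows, columns=["subject_id", "measure", "rate",
                                       "n_timepoints", "span_yr"])
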