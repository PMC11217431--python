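"""Time-stratified case-crossover matching.

Each death day (case) is compared with every other day in the *same calendar
month and year* that falls on the *same day of the week* — three or four
control days, depending on the month.  Because each case is matched to itself
on nearby days, all time-invariant characteristics of the child and household
cancel by design, while the weekday restriction absorbs within-week patterns
and the month/year stratum absorbs seasonality and long-term trends.
"""

from __future__ import annotations

import calendar
import logging
from functools import lru_cache

import numpy as np
import pandas as pd

from .exposure import LagSpec

log = logging.getLogger(__name__)

__all__ = ["control_days", "build_matched_sets"]


@lru_cache(maxsize=None)
def _same_weekday_days(year: int, month: int, weekday: int) -> tuple:
    """Day-of-month numbers in (year, month) falling on ``weekday`` (Mon=0)."""
    first_wd, n_days = calendar.monthrange(year, month)
    first_match = 1 + (weekday - first_wd) % 7
    return tuple(range(first_match, n_days + 1, 7))


def control_days(case_day) -> pd.DatetimeIndex:
    """All same-weekday days in the case day's month/year, case day excluded."""
    ts = pd.Timestamp(case_day)
    days = _same_weekday_days(ts.year, ts.month, ts.weekday())
    return pd.DatetimeIndex(
        [ts.replace(day=d) for d in days if d != ts.day]
    )


def build_matched_sets(deaths: pd.DataFrame, pct_series: dict, lag: LagSpec = LagSpec()) -> pd.DataFrame:
    """Build the matched-set design table for conditional logistic regression.

    Parameters
    ----------
    deaths : DataFrame
        One row per death with columns ``location_id`` and ``death_date``
        (plus anything else, carried through on the case rows' set metadata).
    pct_series : dict
        ``location_id -> pandas.Series`` of daily exposure percentiles.
    lag : LagSpec
        Lag window; each row gains columns x0..xL with the lagged percentiles.

    Returns
    -------
    DataFrame with columns set_id, location_id, date, is_case, x{l0}..x{L}.
    Two deaths on the same day in the same place remain two distinct
    self-matched sets.  Sets whose case or control days lack exposure
    coverage are dropped; the count is logged and stored in
    ``result.attrs["n_dropped"]``.
    """
    rows_date = []
    rows_set = []
    rows_case = []
    rows_loc = []
    d = deaths.reset_index(drop=True)
    dates = pd.DatetimeIndex(pd.to_datetime(d["death_date"]))
    for sid, (loc, ts) in enumerate(zip(d["location_id"], dates)):
        ctrl = control_days(ts)
        n = 1 + len(ctrl)
        rows_set.extend([sid] * n)
        rows_loc.extend([loc] * n)
        rows_date.append(ts)
        rows_date.extend(ctrl)
        rows_case.extend([1] + [0] * len(ctrl))
    out = pd.DataFrame({
        "set_id": np.asarray(rows_set, dtype=int),
        "location_id": rows_loc,
        "date": pd.DatetimeIndex(rows_date),
        "is_case": np.asarray(rows_case, dtype=int),
    })

    xcols = [f"x{l}" for l in lag.lags]
    out[xcols] = np.nan
    for loc, grp in out.groupby("location_id", sort=False):
        pct = pct_series[loc]
        start, arr = pct.index[0], pct.to_numpy()
        offs = (pd.DatetimeIndex(grp["date"]) - start).days.to_numpy()
        ok = (offs - lag.L >= 0) & (offs < arr.size)
        idx = offs[:, None] - lag.lags[None, :]
        vals = np.full((len(grp), lag.n_lags), np.nan)
        vals[ok] = arr[idx[ok]]
        out.loc[grp.index, xcols] = vals

    bad_sets = out.loc[out[xcols].isna().any(axis=1), "set_id"].unique()
    if len(bad_sets):
        log.warning("dropping %d matched sets with incomplete exposure coverage", len(bad_sets))
        out = out[~out["set_id"].isin(bad_sets)].reset_index(drop=True)
    out.attrs["n_dropped"] = int(len(bad_sets))
    return out
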