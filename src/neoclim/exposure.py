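"""Location-specific temperature percentiles and lagged exposure vectors.

Populations spanning different climate zones are pooled by expressing each
day's mean temperature as a percentile of the location's own temperature
distribution, which absorbs adaptation to the local climate.  The empirical
percentile map uses the Hazen plotting position,

    percentile(x) = 100 * (rank(x) - 0.5) / n,

with mid-ranks for ties, so mapped values stay strictly inside (0, 100).
The reference sample is the location's *factual* daily series over the study
period; the counterfactual series is pushed through the same map so that
both scenarios live on one percentile scale and a single fitted
exposure-response curve applies to either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LagSpec", "PercentileMap", "fit_percentile_map", "map_series", "lagged_exposure", "lagged_matrix"]


@dataclass(frozen=True)
class LagSpec:
    """Lag window [l0, L] in days counted backward from the case day."""

    l0: int = 0
    L: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.l0 <= self.L):
            raise ValueError(f"invalid lag window: l0={self.l0}, L={self.L}")

    @property
    def n_lags(self) -> int:
        return self.L - self.l0 + 1

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.l0, self.L + 1)


@dataclass(frozen=True)
class PercentileMap:
    """Empirical Hazen percentile transform for one location.

    ``values``/``positions`` hold the unique sorted reference temperatures and
    their tie-averaged Hazen percentiles; interpolation between them keeps the
    map monotone, and inputs beyond the reference range are clamped to the
    smallest/largest attainable percentile (100*0.5/n and 100*(n-0.5)/n).
    """

    location_id: str
    n: int
    values: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.values, self.positions)

    def inverse(self, p) -> np.ndarray:
        """Temperature at percentile p (linear interpolation of the reference)."""
        return np.interp(np.asarray(p, dtype=float), self.positions, self.values)


def fit_percentile_map(series, location_id: str = "", min_n: int = 365) -> PercentileMap:
    """Fit the Hazen percentile map from a daily reference series.

    Parameters
    ----------
    series : pandas.Series or array-like
        Daily mean temperatures (°C) of the reference sample, normally the
        location's factual series over the full study period.
    min_n : int
        Minimum admissible reference length; shorter samples cannot represent
        the seasonal cycle and are refused.
    """
    temps = np.asarray(getattr(series, "values", series), dtype=float)
    temps = temps[np.isfinite(temps)]
    n = temps.size
    if n < min_n:
        raise ValueError(f"reference sample too short: n={n} < {min_n}")
    order = np.sort(temps)
    # Hazen positions of the sorted sample; ties get the mean position of
    # their block, which equals 100*(midrank - 0.5)/n.
    pos = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    uniq, start = np.unique(order, return_index=True)
    counts = np.diff(np.append(start, n))
    tie_pos = np.add.reduceat(pos, start) / counts
    return PercentileMap(location_id=location_id, n=n, values=uniq, positions=tie_pos)


def map_series(pmap: PercentileMap, series: pd.Series) -> pd.Series:
    """Apply a fitted percentile map to a daily series, preserving the index."""
    return pd.Series(pmap(series.to_numpy()), index=series.index, name="pct")


def lagged_exposure(pct: pd.Series, day, lag: LagSpec) -> np.ndarray:
    """Exposure vector (x_{t-l0}, ..., x_{t-L}) for one case day t."""
    return lagged_matrix(pct, pd.DatetimeIndex([pd.Timestamp(day)]), lag)[0]


def lagged_matrix(pct: pd.Series, days, lag: LagSpec) -> np.ndarray:
    """Lagged exposure vectors for many days at once.

    ``pct`` must be a contiguous daily series; missing coverage of any
    requested (day - l) raises with the offending date named.
    """
    idx = pct.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise TypeError("percentile series must have a DatetimeIndex")
    start = idx[0]
    arr = pct.to_numpy()
    days = pd.DatetimeIndex(days)
    offsets = (days - start).days.to_numpy()
    lags = lag.lags
    need_lo = offsets - lag.L
    need_hi = offsets
    bad = (need_lo < 0) | (need_hi >= arr.size)
    if bad.any():
        d = days[np.argmax(bad)]
        raise ValueError(f"exposure series does not cover lag window of {d.date()}")
    return arr[offsets[:, None] - lags[None, :]]
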