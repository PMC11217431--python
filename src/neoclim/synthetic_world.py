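"""Fully synthetic study world with a known temperature-mortality ground truth.

Generates, from a single seed: a set of study locations with distinct
seasonal climates on a 0.5° grid; daily counterfactual temperature series
(seasonal cycle + AR(1) weather) and factual series obtained by adding a
linear warming ramp that reaches the configured total (default 0.9 °C, the
factual-minus-counterfactual contrast of the study period) at the period end —
so both scenarios share their weather variability by construction; a birth
cohort with day-by-day neonatal survival driven by a known U-shaped,
lag-distributed log-relative-risk surface in percentile space; and the
UNICEF-style per-country rate table realised by that cohort.

Every downstream stage (ingestion, percentile mapping, matching, fitting,
attribution) can therefore be tested against the injected truth without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import ScenarioSeries, write_birth_records, write_temperature_table
from .exposure import fit_percentile_map

__all__ = ["TrueExposureResponse", "ClimateParams", "WorldConfig", "World",
           "generate_temperature_pair", "generate_cohort", "generate_world"]

_PAD_DAYS = 7  # pre-period days so lagged exposures exist for the earliest cases


@dataclass(frozen=True)
class TrueExposureResponse:
    """Ground-truth U-shaped exposure-response in percentile space.

    The cumulative log relative risk is quadratic around the minimum-mortality
    percentile and continues linearly (C1-matched) beyond ``elbow`` percentile
    points from it — a smooth U with straight tails.  ``lag_weights``
    distribute the cumulative effect over lags 0..L and sum to 1, so the
    cumulative curve equals ``log_rr`` itself.
    """

    mmt_percentile: float = 50.0
    amplitude: float = 0.35        # log RR at the elbows (= mmt ± elbow)
    elbow: float = 40.0            # half-width of the quadratic core, percentile points
    lag_weights: tuple = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("lag_weights must sum to 1")
        if abs(self.log_rr(self.mmt_percentile)) > 1e-12:
            raise AssertionError("log RR at the true MMT must be 0")

    def log_rr(self, p) -> np.ndarray:
        u = np.abs(np.asarray(p, dtype=float) - self.mmt_percentile)
        core = self.amplitude * (u / self.elbow) ** 2
        tail = self.amplitude * (1.0 + 2.0 * (u - self.elbow) / self.elbow)
        return np.where(u <= self.elbow, core, tail)

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1


@dataclass(frozen=True)
class ClimateParams:
    """Seasonal climate of one location: mean/amplitude/noise in °C."""

    mean: float
    amplitude: float
    noise_sd: float
    ar_coef: float = 0.7
    peak_doy: float = 196.0  # day of year of the seasonal maximum


@dataclass
class WorldConfig:
    n_locations: int = 10
    start: str = "2001-01-01"
    end: str = "2019-12-31"
    warming: float = 0.9                  # °C reached by the period end
    births_per_location: int = 105_000
    baseline_hazard: float = 0.0012       # daily death probability at the true MMT
    recall_years: int = 15
    psus_per_location: int = 5
    dataset_ids: tuple = ("reanalysis-a",)
    true_surface: TrueExposureResponse = field(default_factory=TrueExposureResponse)
    very_early_surface: TrueExposureResponse | None = None
    climates: tuple | None = None         # optional explicit per-location ClimateParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warming < 0:
            raise ValueError("warming must be non-negative")
        if self.births_per_location < 0:
            raise ValueError("births_per_location must be non-negative")
        if (pd.Timestamp(self.end) - pd.Timestamp(self.start)).days < 730:
            raise ValueError("study period must span at least 2 full years")

    @property
    def location_ids(self) -> list:
        return [f"loc{i:02d}" for i in range(self.n_locations)]

    def climate(self, i: int) -> ClimateParams:
        if self.climates is not None:
            return self.climates[i]
        rng = np.random.default_rng([self.seed, 17, i])
        lat = self.grid().iloc[i]["lat"]
        return ClimateParams(
            mean=float(rng.uniform(13.0, 29.0)),
            amplitude=float(rng.uniform(2.5, 9.0)),
            noise_sd=float(rng.uniform(1.5, 2.5)),
            peak_doy=196.0 if lat >= 0 else 15.0,
        )

    def grid(self) -> pd.DataFrame:
        """Cell-center coordinates on a 0.5° grid, one cell per location."""
        idx = np.arange(self.n_locations)
        return pd.DataFrame({
            "location_id": self.location_ids,
            "lat": -24.75 + 5.0 * idx,
            "lon": 10.25 + 7.0 * (idx % 20),
        })


def generate_temperature_pair(cfg: WorldConfig, location) -> tuple:
    """(factual, counterfactual) ScenarioSeries for one location.

    The counterfactual is generated first (seasonal cycle + AR(1) noise); the
    factual adds a linear ramp of 0 → cfg.warming across the study window,
    which preserves the timing of all weather events in both scenarios.  The
    series start a few days before the study window so lagged exposures exist
    for the earliest case days.
    """
    loc_ids = cfg.location_ids
    i = loc_ids.index(location) if isinstance(location, str) else int(location)
    loc = loc_ids[i]
    clim = cfg.climate(i)

    start = pd.Timestamp(cfg.start) - pd.Timedelta(days=_PAD_DAYS)
    dates = pd.date_range(start, cfg.end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = clim.mean + clim.amplitude * np.cos(2.0 * np.pi * (doy - clim.peak_doy) / 365.25)

    rng = np.random.default_rng([cfg.seed, 23, i])
    innov = rng.normal(0.0, clim.noise_sd * np.sqrt(1.0 - clim.ar_coef**2), size=len(dates))
    noise = np.empty(len(dates))
    noise[0] = rng.normal(0.0, clim.noise_sd)
    for t in range(1, len(dates)):
        noise[t] = clim.ar_coef * noise[t - 1] + innov[t]

    cf_vals = seasonal + noise
    n_study = (pd.Timestamp(cfg.end) - pd.Timestamp(cfg.start)).days + 1
    ramp = np.concatenate([np.zeros(_PAD_DAYS), cfg.warming * np.arange(n_study) / (n_study - 1)])
    fact_vals = cf_vals + ramp

    cf = ScenarioSeries(loc, "", "counterfactual", pd.Series(cf_vals, index=dates, name="tmean"))
    fact = ScenarioSeries(loc, "", "factual", pd.Series(fact_vals, index=dates, name="tmean"))
    return fact, cf


def _daily_multiplier(cfg: WorldConfig, surface: TrueExposureResponse, pct: np.ndarray, pad: int) -> np.ndarray:
    """exp(sum_l w_l * log_rr(x_{t-l})) on the study window (index 0 = period start)."""
    w = np.asarray(surface.lag_weights, dtype=float)
    lr = surface.log_rr(pct)
    n = len(pct) - pad
    acc = np.zeros(n)
    for l, wl in enumerate(w):
        acc += wl * lr[pad - l: pad - l + n]
    return np.exp(acc)


def generate_cohort(cfg: WorldConfig, factual: dict) -> pd.DataFrame:
    """Simulate births and day-by-day neonatal survival under the true surface.

    ``factual`` maps location_id to its factual ScenarioSeries (deaths arise
    from the realised, i.e. factual, climate).  Each child is born uniformly
    in the study period (minus 28 days so the whole risk window is covered),
    and on life-day d the death probability is

        h0 * exp( sum_l lag_weights[l] * log_rr(percentile(day d - l)) ),

    with percentiles from the location's factual map.  Raises if the scaled
    hazard exceeds 1 on any day ("baseline hazard too high").
    """
    rows = []
    n_study = (pd.Timestamp(cfg.end) - pd.Timestamp(cfg.start)).days + 1
    start_ts = pd.Timestamp(cfg.start)
    interview = pd.Timestamp(cfg.end) + pd.Timedelta(days=1)
    grid = cfg.grid().set_index("location_id")

    for i, loc in enumerate(cfg.location_ids):
        ser = factual[loc]
        pad = (start_ts - ser.dates[0]).days
        pmap = fit_percentile_map(ser.tmean.iloc[pad:], location_id=loc)
        pct = pmap(ser.tmean.to_numpy())
        M = _daily_multiplier(cfg, cfg.true_surface, pct, pad)
        if cfg.very_early_surface is not None:
            M0 = _daily_multiplier(cfg, cfg.very_early_surface, pct, pad)
        else:
            M0 = M
        if cfg.baseline_hazard * max(M.max(), M0.max()) >= 1.0:
            raise ValueError("baseline hazard too high: daily death probability would exceed 1")

        n = cfg.births_per_location
        rng = np.random.default_rng([cfg.seed, 31, i])
        birth_off = rng.integers(0, n_study - 28, size=n)
        age = np.full(n, -1, dtype=int)
        chunk = 50_000
        for c0 in range(0, n, chunk):
            c1 = min(c0 + chunk, n)
            b = birth_off[c0:c1]
            days = b[:, None] + np.arange(29)[None, :]
            H = cfg.baseline_hazard * M[days]
            if cfg.very_early_surface is not None:
                H[:, 0] = cfg.baseline_hazard * M0[b]
            died = rng.random((c1 - c0, 29)) < H
            any_death = died.any(axis=1)
            first = np.argmax(died, axis=1)
            age[c0:c1] = np.where(any_death, first, -1)

        glat, glon = grid.loc[loc, ["lat", "lon"]]
        jitter = np.random.default_rng([cfg.seed, 37, i]).uniform(-0.1, 0.1, size=(cfg.psus_per_location, 2))
        psu_idx = np.arange(n) % max(cfg.psus_per_location, 1)
        rows.append(pd.DataFrame({
            "child_id": [f"{loc}-c{j:06d}" for j in range(n)],
            "psu_id": [f"{loc}-psu{p}" for p in psu_idx],
            "birth_date": start_ts + pd.to_timedelta(birth_off, unit="D"),
            "age_at_death_days": np.where(age >= 0, age.astype(float), np.nan),
            "interview_date": interview,
            "lat": glat + (jitter[psu_idx, 0] if n else np.array([])),
            "lon": glon + (jitter[psu_idx, 1] if n else np.array([])),
        }))

    if not rows:
        return pd.DataFrame(columns=["child_id", "psu_id", "birth_date", "age_at_death_days",
                                     "interview_date", "lat", "lon"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class World:
    """A complete synthetic study: cohort, scenario series, grid, rates, truth."""

    config: WorldConfig
    births: pd.DataFrame
    series: dict            # (dataset_id, scenario, location_id) -> ScenarioSeries
    grid: pd.DataFrame
    rates: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_birth_records(self.births, out / "births.csv")
        write_temperature_table(self.series, out / "temps.csv")
        self.grid.to_csv(out / "grid.csv", index=False)
        self.rates.to_csv(out / "country_rates.csv", index=False)
        (out / "truth.yaml").write_text(yaml.safe_dump(self.truth, sort_keys=False))


def generate_world(cfg: WorldConfig) -> World:
    """Generate the full synthetic study, reproducibly from ``cfg.seed``."""
    series = {}
    fact_by_loc = {}
    for loc in cfg.location_ids:
        fact, cf = generate_temperature_pair(cfg, loc)
        fact_by_loc[loc] = fact
        for ds in cfg.dataset_ids:
            series[(ds, "factual", loc)] = ScenarioSeries(loc, ds, "factual", fact.tmean)
            series[(ds, "counterfactual", loc)] = ScenarioSeries(loc, ds, "counterfactual", cf.tmean)

    births = generate_cohort(cfg, fact_by_loc)

    rates_rows = []
    for loc in cfg.location_ids:
        sub = births[births["psu_id"].str.startswith(f"{loc}-")] if len(births) else births
        n = len(sub)
        dead = sub["age_at_death_days"].notna() if n else pd.Series(dtype=bool)
        n_dead = int(dead.sum()) if n else 0
        n_day0 = int((sub["age_at_death_days"] == 0).sum()) if n else 0
        rates_rows.append({
            "country": loc,
            "births": n,
            "m_neonat": 1e5 * n_dead / n if n else np.nan,
            "very_early_share": n_day0 / n_dead if n_dead else np.nan,
        })

    pgrid = np.arange(0.0, 100.5, 0.5)
    truth = {
        "true_mmt_percentile": float(cfg.true_surface.mmt_percentile),
        "lag_weights": [float(w) for w in cfg.true_surface.lag_weights],
        "warming": float(cfg.warming),
        "log_rr_grid": {"percentile": pgrid.tolist(),
                        "log_rr": cfg.true_surface.log_rr(pgrid).tolist()},
    }
    return World(config=cfg, births=births, series=series, grid=cfg.grid(),
                 rates=pd.DataFrame(rates_rows), truth=truth)
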