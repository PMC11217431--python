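"""Readers/writers for the pipeline's flat-file formats and PSU-to-grid linkage.

Formats
-------
births.csv        child_id, psu_id, birth_date, age_at_death_days,
                  interview_date, lat, lon   (dates ISO-8601; age empty if alive)
temps.csv         location_id, dataset_id, scenario, date, tmean   (long format)
temps.nc          CF-style grid (time, lat, lon, tas) — optional, needs xarray
country_rates.csv country, births, m_neonat, very_early_share
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BIRTH_COLUMNS = ["child_id", "psu_id", "birth_date", "age_at_death_days", "interview_date", "lat", "lon"]
TEMP_COLUMNS = ["location_id", "dataset_id", "scenario", "date", "tmean"]
RATE_COLUMNS = ["country", "births", "m_neonat", "very_early_share"]

EARTH_RADIUS_KM = 6371.0


class SchemaError(ValueError):
    """A mandatory column is missing or mistyped."""


@dataclass
class ScenarioSeries:
    """Daily mean temperature for one location under one scenario.

    ``tmean`` is a pandas Series with a contiguous daily DatetimeIndex.
    """

    location_id: str
    dataset_id: str
    scenario: str  # "factual" | "counterfactual"
    tmean: pd.Series

    def __post_init__(self) -> None:
        idx = self.tmean.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if (deltas != 1).any():
                raise ValueError(
                    f"series {self.location_id}/{self.dataset_id}/{self.scenario} "
                    "is not contiguous daily"
                )

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.tmean.index


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def read_birth_records(path, return_rejected: bool = False):
    """Read a births table, rejecting invalid rows with a row-numbered report.

    Rows are rejected (not fatal) when a date fails to parse, when
    age_at_death_days is negative, or when birth_date > interview_date.
    A missing mandatory column raises :class:`SchemaError`.
    """
    raw = pd.read_csv(path, dtype={"child_id": str, "psu_id": str})
    _require_columns(raw, BIRTH_COLUMNS, f"births file {path}")
    birth = pd.to_datetime(raw["birth_date"], format="%Y-%m-%d", errors="coerce")
    interview = pd.to_datetime(raw["interview_date"], format="%Y-%m-%d", errors="coerce")
    age = pd.to_numeric(raw["age_at_death_days"], errors="coerce")

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[birth.isna()] = "unparseable birth_date"
    reasons[interview.isna()] = "unparseable interview_date"
    has_age_field = raw["age_at_death_days"].notna() & (raw["age_at_death_days"].astype(str).str.strip() != "")
    reasons[has_age_field & age.isna()] = "unparseable age_at_death_days"
    reasons[(age < 0).fillna(False)] = "negative age_at_death_days"
    ok_dates = birth.notna() & interview.notna()
    reasons[ok_dates & (birth > interview)] = "birth_date after interview_date"

    bad = reasons != ""
    rejected = pd.DataFrame({"row": raw.index[bad] + 2, "reason": reasons[bad]})  # +2: header + 1-based
    for _, r in rejected.iterrows():
        log.warning("births row %d rejected: %s", r["row"], r["reason"])

    records = raw.loc[~bad].copy()
    records["birth_date"] = birth[~bad]
    records["interview_date"] = interview[~bad]
    records["age_at_death_days"] = age[~bad]
    records["lat"] = records["lat"].astype(float)
    records["lon"] = records["lon"].astype(float)
    records = records.reset_index(drop=True)
    if return_rejected:
        return records, rejected.reset_index(drop=True)
    return records


def write_birth_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out["interview_date"] = pd.to_datetime(out["interview_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=[c for c in BIRTH_COLUMNS if c in out.columns])


def select_deaths(records: pd.DataFrame, window: str = "neonatal", recall_years: int = 15) -> pd.DataFrame:
    """Select the death records for one outcome within the maternal recall window.

    ``neonatal`` keeps deaths at age 0–28 days; ``very_early`` keeps deaths on
    the day of delivery (age 0).  Deaths whose death date precedes
    interview_date minus ``recall_years`` years are dropped: long-recalled
    events are the least reliably dated in retrospective birth histories.
    The returned table gains a ``death_date`` column (birth + age in days).
    """
    if window == "neonatal":
        keep = records["age_at_death_days"].between(0, 28)
    elif window == "very_early":
        keep = records["age_at_death_days"] == 0
    else:
        raise ValueError(f"unknown outcome window: {window!r}")
    deaths = records.loc[keep.fillna(False)].copy()
    deaths["death_date"] = pd.to_datetime(deaths["birth_date"]) + pd.to_timedelta(
        deaths["age_at_death_days"].astype(int), unit="D"
    )
    cutoff = pd.to_datetime(deaths["interview_date"]) - pd.DateOffset(years=recall_years)
    return deaths.loc[deaths["death_date"] >= cutoff].reset_index(drop=True)


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (haversine), broadcasting over inputs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def link_to_grid(records: pd.DataFrame, grid: pd.DataFrame, max_km: float = 100.0) -> pd.DataFrame:
    """Assign each PSU the temperature location whose cell center is nearest.

    ``grid`` has columns location_id, lat, lon.  Ties in great-circle distance
    break to the lexicographically smallest location_id, so the assignment is
    deterministic and invariant to row order.  PSUs farther than ``max_km``
    from every cell center raise with the offending PSUs listed.
    """
    _require_columns(grid, ["location_id", "lat", "lon"], "grid table")
    psus = records[["psu_id", "lat", "lon"]].drop_duplicates("psu_id").sort_values("psu_id")
    g = grid.sort_values("location_id").reset_index(drop=True)
    d = great_circle_km(
        psus["lat"].to_numpy()[:, None], psus["lon"].to_numpy()[:, None],
        g["lat"].to_numpy()[None, :], g["lon"].to_numpy()[None, :],
    )
    # round distances so that numerically equal distances tie exactly, then
    # argmin picks the first (= lowest location_id after the sort above)
    dr = np.round(d, 6)
    j = np.argmin(dr, axis=1)
    dmin = dr[np.arange(len(psus)), j]
    too_far = dmin > max_km
    if too_far.any():
        bad = psus["psu_id"].to_numpy()[too_far]
        raise ValueError(f"PSU(s) farther than {max_km} km from any grid cell: {sorted(bad)}")
    assign = pd.DataFrame({"psu_id": psus["psu_id"].to_numpy(), "location_id": g["location_id"].to_numpy()[j]})
    out = records.merge(assign, on="psu_id", how="left", suffixes=("", "_linked"))
    if "location_id_linked" in out.columns:
        out["location_id"] = out.pop("location_id_linked")
    return out


def read_temperature_table(path) -> dict:
    """Read a long-format temps.csv into {(dataset, scenario, location): ScenarioSeries}."""
    df = pd.read_csv(path, dtype={"location_id": str, "dataset_id": str, "scenario": str})
    _require_columns(df, TEMP_COLUMNS, f"temperature file {path}")
    df["date"] = pd.to_datetime(df["date"])
    out = {}
    for (ds, sc, loc), grp in df.groupby(["dataset_id", "scenario", "location_id"], sort=True):
        grp = grp.sort_values("date")
        s = pd.Series(grp["tmean"].to_numpy(float), index=pd.DatetimeIndex(grp["date"]), name="tmean")
        out[(ds, sc, loc)] = ScenarioSeries(loc, ds, sc, s)
    return out


def write_temperature_table(series_map: dict, path) -> None:
    frames = []
    for (ds, sc, loc), ser in sorted(series_map.items()):
        frames.append(pd.DataFrame({
            "location_id": loc, "dataset_id": ds, "scenario": sc,
            "date": ser.dates.strftime("%Y-%m-%d"), "tmean": ser.tmean.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_temperature_grid(path, dataset_id: str, scenario: str) -> dict:
    """Read a CF-style NetCDF grid (time, lat, lon, tas) into ScenarioSeries.

    Each (lat, lon) cell becomes one location named ``"{lat:.2f}_{lon:.2f}"``.
    Kelvin is converted to °C when the declared units say K.
    """
    import xarray as xr  # optional dependency

    ds = xr.open_dataset(path)
    tas = ds["tas"]
    if str(tas.attrs.get("units", "")).strip().lower() in {"k", "kelvin"}:
        tas = tas - 273.15
    out = {}
    for lat in np.atleast_1d(ds["lat"].values):
        for lon in np.atleast_1d(ds["lon"].values):
            loc = f"{float(lat):.2f}_{float(lon):.2f}"
            vals = tas.sel(lat=lat, lon=lon).to_series()
            vals.index = pd.DatetimeIndex(vals.index).normalize()
            out[(dataset_id, scenario, loc)] = ScenarioSeries(loc, dataset_id, scenario, vals.rename("tmean"))
    return out


def grid_table(series_map: dict, grid_coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Location table (location_id, lat, lon) for linkage, from explicit coords."""
    if grid_coords is not None:
        _require_columns(grid_coords, ["location_id", "lat", "lon"], "grid table")
        return grid_coords
    raise ValueError("grid coordinates required for CSV temperature input")


def read_country_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country": str})
    _require_columns(df, RATE_COLUMNS, f"country rates file {path}")
    if (df["m_neonat"] <= 0).any():
        raise ValueError("m_neonat must be positive")
    if ((df["very_early_share"] <= 0) | (df["very_early_share"] >= 1)).any():
        raise ValueError("very_early_share must be in (0, 1)")
    return df


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_run_metadata(path, seed: int, config: dict) -> None:
    """JSON sidecar recording seed, package version and config hash."""
    from . import __version__

    meta = {"seed": seed, "neoclim_version": __version__, "config_hash": config_hash(config), "config": config}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
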