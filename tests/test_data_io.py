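import numpy as np
import pandas as pd
import pytest

from neoclim import data_io


@pytest.fixture()
def births_csv(tmp_path):
    p = tmp_path / "births.csv"
    p.write_text(
        "child_id,psu_id,birth_date,age_at_death_days,interview_date,lat,lon\n"
        "c1,p1,2015-03-01,5,2019-01-01,10.25,20.25\n"
        "c2,p1,2016-07-12,,2019-01-01,10.25,20.25\n"
        "c3,p2,2017-11-30,0,2019-01-01,10.75,20.25\n"
    )
    return p


class TestReadBirths:
    def test_well_formed_rows(self, births_csv):
        rec = data_io.read_birth_records(births_csv)
        assert len(rec) == 3
        assert rec["birth_date"].dtype.kind == "M"
        assert np.isnan(rec["age_at_death_days"].iloc[1])

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("child_id,psu_id,birth_date,interview_date,lat,lon\nc1,p1,2015-01-01,2019-01-01,0,0\n")
        with pytest.raises(data_io.SchemaError, match="age_at_death_days"):
            data_io.read_birth_records(p)

    def test_invalid_rows_rejected_with_report(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text(
            "child_id,psu_id,birth_date,age_at_death_days,interview_date,lat,lon\n"
            "c1,p1,2015-03-01,-1,2019-01-01,0,0\n"          # negative age
            "c2,p1,not-a-date,3,2019-01-01,0,0\n"           # bad date
            "c3,p1,2020-01-01,3,2019-01-01,0,0\n"           # birth after interview
            "c4,p1,2015-03-01,3,2019-01-01,0,0\n"
        )
        rec, rej = data_io.read_birth_records(p, return_rejected=True)
        assert list(rec["child_id"]) == ["c4"]
        assert sorted(rej["row"]) == [2, 3, 4]
        assert any("negative" in r for r in rej["reason"])

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("child_id,psu_id,birth_date,age_at_death_days,interview_date,lat,lon\n")
        assert len(data_io.read_birth_records(p)) == 0

    def test_roundtrip_lossless(self, births_csv, tmp_path):
        rec = data_io.read_birth_records(births_csv)
        out = tmp_path / "out.csv"
        data_io.write_birth_records(rec, out)
        again = data_io.read_birth_records(out)
        pd.testing.assert_frame_equal(rec, again)


class TestSelectDeaths:
    @pytest.fixture()
    def records(self):
        ages = [0, 5, 28, 29, np.nan]
        return pd.DataFrame({
            "child_id": [f"c{i}" for i in range(5)],
            "psu_id": "p1",
            "birth_date": pd.Timestamp("2015-06-01"),
            "age_at_death_days": ages,
            "interview_date": pd.Timestamp("2019-01-01"),
            "lat": 0.0, "lon": 0.0,
        })

    def test_neonatal_window_is_0_to_28_days(self, records):
        got = data_io.select_deaths(records, "neonatal")
        assert sorted(got["age_at_death_days"]) == [0, 5, 28]

    def test_very_early_keeps_day_of_delivery_only(self, records):
        got = data_io.select_deaths(records, "very_early")
        assert list(got["age_at_death_days"]) == [0]

    def test_recall_window_drops_old_deaths(self, records):
        got = data_io.select_deaths(records, "neonatal", recall_years=5)
        assert len(got) == 3  # mid-2015 deaths are within 5y of 2019-01-01
        old = records.assign(birth_date=pd.Timestamp("2012-06-01"))
        assert len(data_io.select_deaths(old, "neonatal", recall_years=5)) == 0

    def test_death_date_reconstruction(self, records):
        got = data_io.select_deaths(records, "neonatal")
        expect = pd.Timestamp("2015-06-01") + pd.Timedelta(days=28)
        assert got.loc[got["age_at_death_days"] == 28, "death_date"].iloc[0] == expect


class TestLinkToGrid:
    grid = pd.DataFrame({"location_id": ["a", "b"], "lat": [0.25, 0.25], "lon": [20.25, 20.75]})

    def rec(self, lat, lon, psu="p1"):
        return pd.DataFrame({"child_id": ["c"], "psu_id": [psu], "birth_date": [pd.Timestamp("2015-01-01")],
                             "age_at_death_days": [1.0], "interview_date": [pd.Timestamp("2019-01-01")],
                             "lat": [lat], "lon": [lon]})

    def test_psu_at_cell_center(self):
        got = data_io.link_to_grid(self.rec(0.25, 20.75), self.grid)
        assert got["location_id"].iloc[0] == "b"

    def test_equidistant_tie_breaks_to_lowest_id(self):
        got = data_io.link_to_grid(self.rec(0.25, 20.50), self.grid)
        assert got["location_id"].iloc[0] == "a"

    def test_far_psu_raises_listing_it(self):
        with pytest.raises(ValueError, match="p-ocean"):
            data_io.link_to_grid(self.rec(-40.0, -120.0, psu="p-ocean"), self.grid, max_km=100)

    def test_permutation_invariant_and_idempotent(self):
        recs = pd.concat([self.rec(0.3, 20.3, "p1"), self.rec(0.2, 20.7, "p2")], ignore_index=True)
        a = data_io.link_to_grid(recs, self.grid)
        b = data_io.link_to_grid(recs.iloc[::-1].reset_index(drop=True), self.grid)
        merged = a.merge(b[["psu_id", "location_id"]], on="psu_id", suffixes=("", "_b"))
        assert (merged["location_id"] == merged["location_id_b"]).all()
        again = data_io.link_to_grid(a, self.grid)
        assert (again["location_id"] == a["location_id"]).all()


class TestTemperatureIO:
    def test_csv_roundtrip(self, tmp_path, small_world):
        p = tmp_path / "temps.csv"
        data_io.write_temperature_table(small_world.series, p)
        back = data_io.read_temperature_table(p)
        assert set(back) == set(small_world.series)
        k = next(iter(back))
        np.testing.assert_allclose(back[k].tmean.to_numpy(),
                                   small_world.series[k].tmean.to_numpy(), atol=1e-9)

    def test_non_contiguous_series_rejected(self):
        idx = pd.DatetimeIndex(["2015-01-01", "2015-01-03"])
        with pytest.raises(ValueError, match="contiguous"):
            data_io.ScenarioSeries("x", "d", "factual", pd.Series([1.0, 2.0], index=idx))

    def test_netcdf_grid_reader_kelvin(self, tmp_path):
        xr = pytest.importorskip("xarray")
        time = pd.date_range("2015-01-01", periods=10, freq="D")
        ds = xr.Dataset({"tas": (("time", "lat", "lon"),
                                 290.0 + np.zeros((10, 1, 1)))},
                        coords={"time": time, "lat": [0.25], "lon": [20.25]})
        ds["tas"].attrs["units"] = "K"
        p = tmp_path / "t.nc"
        ds.to_netcdf(p, engine="scipy")
        got = data_io.read_temperature_grid(p, "ds1", "factual")
        ser = got[("ds1", "factual", "0.25_20.25")]
        np.testing.assert_allclose(ser.tmean.to_numpy(), 290.0 - 273.15)


def test_country_rates_validation(tmp_path):
    p = tmp_path / "rates.csv"
    p.write_text("country,births,m_neonat,very_early_share\nA,1000,2000,0.4\n")
    df = data_io.read_country_rates(p)
    assert df["m_neonat"].iloc[0] == 2000
    p.write_text("country,births,m_neonat,very_early_share\nA,1000,-5,0.4\n")
    with pytest.raises(ValueError):
        data_io.read_country_rates(p)
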