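import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from transpirest import experiment_io
from transpirest.errors import CoverageError, DataValidationError, ParseError
from transpirest.experiment_io import (
    ClimateLog,
    ProtocolConfig,
    WeighingSeries,
    mean_climate,
    read_climate_csv,
    read_weighing_csv,
    write_climate_csv,
    write_weighing_csv,
)

T0 = pd.Timestamp("2024-03-01T08:00:00")


def _series(hours, masses, **kw):
    return WeighingSeries(
        item_id="a1",
        timestamps=T0 + pd.to_timedelta(hours, unit="h"),
        mass_g=np.asarray(masses, float),
        **kw,
    )


class TestWeighingSeries:
    def test_duration_and_net_mass(self):
        s = _series([0, 12, 24], [131.0, 130.8, 130.6], container_tare_g=30.0)
        assert s.duration_h == 24.0
        assert s.net_mass_g[0] == pytest.approx(101.0)

    @pytest.mark.parametrize(
        "hours, masses",
        [
            ([0], [131.0]),  # too short
            ([0, 24, 12], [131.0, 130.8, 130.9]),  # non-monotone time
            ([0, 0, 24], [131.0, 130.9, 130.8]),  # duplicate timestamp
            ([0, 24], [131.0, np.nan]),  # non-finite mass
        ],
    )
    def test_invalid_series_rejected(self, hours, masses):
        with pytest.raises(DataValidationError):
            _series(hours, masses)

    def test_mass_must_exceed_tare(self):
        with pytest.raises(DataValidationError, match="tare"):
            _series([0, 24], [131.0, 130.8], container_tare_g=131.0)


class TestClimateLog:
    def test_humidity_bounds_enforced(self):
        with pytest.raises(DataValidationError, match="humidity"):
            ClimateLog(
                data=pd.DataFrame(
                    {"timestamp": [T0, T0 + pd.Timedelta(hours=1)],
                     "temp_c": [20.0, 20.0], "rh_pct": [50.0, 101.0]}
                )
            )

    def test_missing_column_rejected(self):
        with pytest.raises(DataValidationError, match="missing columns"):
            ClimateLog(data=pd.DataFrame({"timestamp": [T0], "temp_c": [20.0]}))


class TestCsvRoundTrip:
    def test_weighing_round_trip_is_exact(self, tmp_path):
        series = {
            "a1": _series([0, 2, 24], [131.2472, 131.2161, 130.8751]),
            "a2": _series([0, 2, 24], [118.9, 118.87, 118.51]),
        }
        series["a2"].item_id = "a2"
        path = tmp_path / "weigh.csv"
        write_weighing_csv(series, path)
        back = read_weighing_csv(path)
        assert set(back) == {"a1", "a2"}
        for key in back:
            np.testing.assert_array_equal(back[key].mass_g, series[key].mass_g)
            assert (back[key].timestamps == series[key].timestamps).all()

    def test_climate_round_trip_is_exact(self, tmp_path, climate_20_50):
        path = tmp_path / "climate.csv"
        write_climate_csv(climate_20_50, path)
        back = read_climate_csv(path)
        pd.testing.assert_frame_equal(back.data, climate_20_50.data)

    def test_minimal_two_row_file(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "item_id,timestamp,mass_g\n"
            "a1,2024-03-01T08:00:00,131.2472\n"
            "a1,2024-03-02T08:00:00,130.8751\n"
        )
        series = read_weighing_csv(path)
        assert len(series["a1"].mass_g) == 2

    def test_decreasing_timestamps_rejected(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "item_id,timestamp,mass_g\n"
            "a1,2024-03-02T08:00:00,130.8751\n"
            "a1,2024-03-01T08:00:00,131.2472\n"
        )
        with pytest.raises(DataValidationError, match="not increasing"):
            read_weighing_csv(path)

    def test_duplicate_item_timestamp_rejected(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "item_id,timestamp,mass_g\n"
            "a1,2024-03-01T08:00:00,131.2472\n"
            "a1,2024-03-01T08:00:00,131.2470\n"
        )
        with pytest.raises(DataValidationError, match="duplicate"):
            read_weighing_csv(path)

    @pytest.mark.parametrize("bad_mass", ["-3.0", ""])
    def test_bad_mass_rejected(self, tmp_path, bad_mass):
        path = tmp_path / "w.csv"
        path.write_text(
            "item_id,timestamp,mass_g\n"
            f"a1,2024-03-01T08:00:00,{bad_mass}\n"
            "a1,2024-03-02T08:00:00,130.8751\n"
        )
        with pytest.raises(DataValidationError):
            read_weighing_csv(path)

    def test_schema_mismatch_names_columns(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("fruit,when,grams\na,b,c\n")
        with pytest.raises(ParseError, match="missing columns"):
            read_weighing_csv(path)

    def test_unparseable_timestamp(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("timestamp,temp_c,rh_pct\nyesterday,20,50\ntoday,20,50\n")
        with pytest.raises(ParseError, match="timestamp"):
            read_climate_csv(path)


class TestMeanClimate:
    def test_constant_log(self, climate_20_50):
        t, rh, p = mean_climate(climate_20_50, T0.replace(day=1, month=1, year=2024),
                                pd.Timestamp("2024-01-01T20:00:00"))
        assert (t, rh, p) == (20.0, 50.0, 101325.0)

    def test_two_equal_halves_average(self):
        # 19 degC for the first half, 21 for the second, symmetric ramp at noon
        ts = pd.Timestamp("2024-01-01") + pd.to_timedelta([0, 11, 13, 24], unit="h")
        log = ClimateLog(
            data=pd.DataFrame(
                {"timestamp": ts, "temp_c": [19.0, 19.0, 21.0, 21.0],
                 "rh_pct": [50.0] * 4}
            )
        )
        t, rh, p = mean_climate(log, ts[0], ts[-1])
        assert t == pytest.approx(20.0, abs=1e-12)
        assert p is None  # no pressure column logged

    def test_irregular_sampling_matches_dense_integration_oracle(self):
        rng = np.random.default_rng(42)
        t_h = np.sort(np.concatenate(([0.0, 24.0], rng.uniform(0, 24, 30))))
        temp = 20.0 + rng.normal(0, 0.5, t_h.size)
        ts = pd.Timestamp("2024-01-01") + pd.to_timedelta(t_h, unit="h")
        log = ClimateLog(
            data=pd.DataFrame({"timestamp": ts, "temp_c": temp, "rh_pct": 50.0})
        )
        w0, w1 = ts[0] + pd.Timedelta(hours=1.3), ts[-1] - pd.Timedelta(hours=2.7)
        got, _, _ = mean_climate(log, w0, w1)

        # oracle: brute-force trapezoid on a grid containing every sample knot
        a = (w0 - ts[0]).total_seconds() / 3600.0
        b = (w1 - ts[0]).total_seconds() / 3600.0
        grid = np.unique(np.concatenate((np.linspace(a, b, 5000), t_h)))
        grid = grid[(grid >= a) & (grid <= b)]
        oracle = np.trapezoid(np.interp(grid, t_h, temp), grid) / (b - a)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_window_outside_coverage(self, climate_20_50):
        with pytest.raises(CoverageError):
            mean_climate(
                climate_20_50,
                pd.Timestamp("2023-12-31T00:00:00"),
                pd.Timestamp("2024-01-01T12:00:00"),
            )


class TestProtocolConfig:
    def test_duration_defaults_follow_protocol(self):
        assert ProtocolConfig(protocol="free").min_duration_h == 24.0
        assert ProtocolConfig(
            protocol="bulk", tissue_resistance_s_cm=363.0
        ).min_duration_h == 48.0

    def test_bulk_requires_tissue_resistance(self):
        with pytest.raises(ValidationError, match="tissue_resistance"):
            ProtocolConfig(protocol="bulk")

    def test_water_activity_bounds(self):
        with pytest.raises(ValidationError):
            ProtocolConfig(aw=1.5)
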