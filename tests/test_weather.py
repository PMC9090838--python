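"""Weather derivation: astronomy, Angstrom-Prescott, Tetens, wind, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

import chingke as ck
from chingke.weather import (
    ANGSTROM_A,
    ANGSTROM_B,
    angstrom_radiation,
    extraterrestrial_radiation,
    read_cabo_weather,
    saturation_vapor_pressure,
    seasonal_summary,
    wind_at_2m,
    write_cabo_weather,
)


def fao56_oracle(lat_deg, doy):
    """Step-by-step FAO-56 astronomical computation, kept independent of the
    production routine (explicit scalar arithmetic, no shared helpers)."""
    gsc = 0.0820  # MJ/m2/min
    phi = lat_deg * math.pi / 180.0
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    dec = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    ws = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(dec))))
    ra_mj = (
        24 * 60 / math.pi * gsc * dr
        * (ws * math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.sin(ws))
    )
    return ra_mj * 1000.0, 24.0 / math.pi * ws


class TestAstronomy:
    def test_matches_independent_fao56_evaluation(self):
        for lat, doy in [(29.65, 172), (35.0, 80), (28.0, 355), (38.0, 100), (0.0, 200)]:
            ra, n = extraterrestrial_radiation(lat, doy)
            ra_o, n_o = fao56_oracle(lat, doy)
            assert ra == pytest.approx(ra_o, rel=1e-12)
            assert n == pytest.approx(n_o, rel=1e-12)

    def test_equator_equinox_daylength(self):
        _, n = extraterrestrial_radiation(0.0, 80)
        assert n == pytest.approx(12.0, abs=0.2)

    def test_northern_solstice_ordering(self):
        ra_summer, n_summer = extraterrestrial_radiation(45.0, 172)
        ra_winter, n_winter = extraterrestrial_radiation(45.0, 355)
        assert ra_summer > ra_winter
        assert n_summer > n_winter

    def test_latitude_domain_error(self):
        with pytest.raises(ValueError):
            extraterrestrial_radiation(95.0, 100)


class TestAngstrom:
    def test_full_sunshine_limit(self):
        assert angstrom_radiation(12.0, 12.0, 1000.0) == pytest.approx(820.0)

    def test_overcast_limit(self):
        assert angstrom_radiation(0.0, 12.0, 1000.0) == pytest.approx(270.0)

    def test_half_sunshine_direct_value(self):
        assert angstrom_radiation(6.0, 12.0, 30000.0) == pytest.approx(16350.0)

    def test_bounds_hold_for_any_sunshine(self):
        ra_max = 30000.0
        for frac in np.linspace(0, 1, 11):
            ra = angstrom_radiation(frac * 12.0, 12.0, ra_max)
            assert ANGSTROM_A * ra_max - 1e-9 <= ra <= (ANGSTROM_A + ANGSTROM_B) * ra_max + 1e-9

    def test_polar_night_convention_and_data_error(self):
        assert angstrom_radiation(0.0, 0.0, 500.0) == pytest.approx(135.0)
        with pytest.raises(ValueError):
            angstrom_radiation(1.0, 0.0, 500.0)


class TestVapourPressure:
    def test_tetens_reference_points(self):
        assert saturation_vapor_pressure(20.0) == pytest.approx(2.339, abs=2e-3)
        assert saturation_vapor_pressure(0.0) == pytest.approx(0.6108, abs=1e-4)

    def test_monotone_in_temperature(self):
        temps = np.linspace(-40, 50, 50)
        vals = [saturation_vapor_pressure(t) for t in temps]
        assert np.all(np.diff(vals) > 0)

    def test_actual_vapor_pressure_cases(self):
        tx, tn = 25.0, 5.0
        e_tx = saturation_vapor_pressure(tx)
        e_tn = saturation_vapor_pressure(tn)
        assert ck.actual_vapor_pressure(100.0, tx, tn) == pytest.approx((e_tx + e_tn) / 2)
        assert ck.actual_vapor_pressure(0.0, tx, tn) == 0.0
        assert ck.actual_vapor_pressure(50.0, tx, tn) == pytest.approx(0.5 * (e_tx + e_tn) / 2)

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ck.actual_vapor_pressure(120.0, 20.0, 5.0)


class TestWind:
    def test_reference_value(self):
        assert wind_at_2m(10.0) == pytest.approx(10.0 * 0.2**0.16, rel=1e-12)

    def test_zero_and_linearity(self):
        assert wind_at_2m(0.0) == 0.0
        assert wind_at_2m(3.0 * 2.5) == pytest.approx(3.0 * wind_at_2m(2.5), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            wind_at_2m(-1.0)


class TestDeriveDaily:
    def test_tdr_and_imputation(self):
        raw = pd.DataFrame({
            "station_id": ["X"] * 2,
            "date": ["2001-06-01", "2001-06-02"],
            "tave": [14.0, np.nan],
            "tmax": [20.0, 22.0],
            "tmin": [8.0, 10.0],
            "sunshine_h": [8.0, 6.0],
            "wind10": [3.0, 2.0],
            "rh": [50.0, 60.0],
            "precip": [0.0, 1.0],
        })
        meta = ck.StationMeta("X", "x", 30.0, 90.0, 3000.0, "Chaiqing-1")
        d = ck.derive_daily(raw, meta)
        assert list(d["tdr"]) == [12.0, 12.0]
        assert d["tave"].iloc[1] == pytest.approx(16.0)  # (22+10)/2
        assert np.all(d["ra"] <= d["ra_max"] * (ANGSTROM_A + ANGSTROM_B) + 1e-9)
        assert np.all(d["ra"] >= d["ra_max"] * ANGSTROM_A - 1e-9)

    def test_unusable_rows_dropped(self):
        raw = pd.DataFrame({
            "station_id": ["X"] * 2,
            "date": ["2001-06-01", "2001-06-02"],
            "tave": [14.0, 15.0],
            "tmax": [20.0, 9.0],
            "tmin": [8.0, 10.0],  # inverted on day 2
            "sunshine_h": [8.0, 6.0],
            "wind10": [3.0, 2.0],
            "rh": [50.0, 60.0],
            "precip": [0.0, 1.0],
        })
        meta = ck.StationMeta("X", "x", 30.0, 90.0, 3000.0, "Chaiqing-1")
        d = ck.derive_daily(raw, meta)
        assert len(d) == 1

    def test_derived_archive_invariants(self, derived_station):
        _, d = derived_station
        assert (d["tmin"] <= d["tmax"]).all()
        assert (d["tdr"] >= 0).all()
        assert (d["ra"] <= d["ra_max"] + 1e-9).all()
        assert d["daylength"].between(0, 24).all()


class TestSeasonalSummary:
    def test_constant_series_hand_sums(self, constant_weather):
        w = constant_weather(tave=10.0)
        w["station_id"] = "X"
        s = seasonal_summary(w, (pd.Timestamp("2001-05-01"), pd.Timestamp("2001-08-08")))
        assert s.eat == pytest.approx(100 * 10.0)  # 100 days at 10 °C
        assert s.tave == pytest.approx(10.0)
        assert s.ra_total == pytest.approx(100 * 20000.0 * 1e-3)

    def test_negative_temperatures_truncated(self, constant_weather):
        w = constant_weather(tave=-5.0)
        w["station_id"] = "X"
        s = seasonal_summary(w, (pd.Timestamp("2001-05-01"), pd.Timestamp("2001-06-30")))
        assert s.eat == 0.0

    def test_eat_additive_over_adjacent_windows(self, derived_station):
        _, d = derived_station
        a = seasonal_summary(d, ("2002-04-01", "2002-06-30"))
        b = seasonal_summary(d, ("2002-07-01", "2002-09-30"))
        c = seasonal_summary(d, ("2002-04-01", "2002-09-30"))
        assert a.eat + b.eat == pytest.approx(c.eat, rel=1e-12)
        assert s_total_close(a.ra_total + b.ra_total, c.ra_total)

    def test_annual_at0_bounds_window_eat(self, derived_station):
        _, d = derived_station
        s = seasonal_summary(d, ("2002-04-10", "2002-09-30"))
        assert s.annual_at0 >= s.eat

    def test_empty_window_rejected(self, derived_station):
        _, d = derived_station
        with pytest.raises(ValueError):
            seasonal_summary(d, ("2002-06-01", "2002-05-01"))


def s_total_close(x, y):
    return x == pytest.approx(y, rel=1e-12)


class TestCaboRoundTrip:
    def test_write_read_identity_at_declared_precision(self, derived_station, tmp_path):
        _, d = derived_station
        path = tmp_path / "st.wth"
        write_cabo_weather(d, "ST1", path)
        back = read_cabo_weather(path)
        assert len(back) == len(d)
        assert np.allclose(back["tmin"], d["tmin"].round(2))
        assert np.allclose(back["tmax"], d["tmax"].round(2))
        assert np.allclose(back["irrad_kj"], d["ra"].round(1))
        assert np.allclose(back["vap_kpa"], d["ea"].round(4))
        assert (back["date"].to_numpy() == d["date"].to_numpy()).all()
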