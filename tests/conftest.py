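import numpy as np
import pandas as pd
import pytest

import chingke as ck
from chingke.weather import derive_daily


@pytest.fixture(scope="session")
def small_archive():
    """A 3-station, 6-year synthetic raw archive plus metadata."""
    cfg = ck.WeatherGenConfig(seed=42, n_stations=3, year_start=2000, year_end=2005)
    meta, daily = ck.gen_station_weather(cfg)
    return meta, daily


@pytest.fixture(scope="session")
def derived_station(small_archive):
    """Derived daily series + metadata for the first synthetic station."""
    meta, daily = small_archive
    row = meta.iloc[0]
    m = ck.StationMeta(
        station_id=row.station_id, name=row["name"], latitude=row.lat,
        longitude=row.lon, elevation=row.elev, variety=row.variety,
    )
    d = derive_daily(daily[daily.station_id == m.station_id], m)
    return m, d


@pytest.fixture()
def constant_weather():
    """One season of constant, benign weather for phenology oracles."""

    def make(tave=10.0, tdr=10.0, ra=20000.0, year=2001, daylength=13.0):
        dates = pd.date_range(f"{year}-04-01", f"{year}-10-31", freq="D")
        return pd.DataFrame({
            "date": dates,
            "tave": tave,
            "tmax": tave + tdr / 2,
            "tmin": tave - tdr / 2,
            "ra": ra,
            "daylength": daylength,
        })

    return make
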