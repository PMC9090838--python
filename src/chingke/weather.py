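"""Daily weather preprocessing for potential-production crop simulation.

Raw station observations (temperatures, sunshine hours, 10-m wind, relative
humidity, precipitation) are turned into the quantities the crop simulator
needs: global solar radiation via the Angstrom–Prescott relation driven by
FAO-56 extraterrestrial radiation, actual vapour pressure via the Tetens
saturation curve, wind rescaled from 10 m to 2 m with a power-law profile,
and the diurnal temperature range.  Seasonal aggregates (mean temperatures,
effective accumulated temperature, seasonal radiation total) feed the trend
and attribution stages.

Internally radiation is carried in kJ/m²/day; seasonal totals are reported
in MJ/m².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StationMeta",
    "SeasonalSummary",
    "extraterrestrial_radiation",
    "angstrom_radiation",
    "saturation_vapor_pressure",
    "actual_vapor_pressure",
    "wind_at_2m",
    "derive_daily",
    "seasonal_summary",
    "read_station_csv",
    "read_station_meta",
    "write_cabo_weather",
    "read_cabo_weather",
    "ANGSTROM_A",
    "ANGSTROM_B",
]

log = logging.getLogger(__name__)

#: Angstrom–Prescott coefficients recommended for high-altitude plateau
#: stations: clear-sky fraction reaches a + b = 0.82 of the extraterrestrial
#: radiation, overcast days retain a = 0.27.
ANGSTROM_A = 0.27
ANGSTROM_B = 0.55

#: Power-law exponent of the near-surface wind profile used to rescale the
#: 10-m anemometer record to the 2-m reference height.
WIND_PROFILE_ALPHA = 0.16

#: Solar constant, kJ/m²/min (FAO-56 value 0.0820 MJ).
_GSC_KJ_MIN = 82.0


@dataclass(frozen=True)
class StationMeta:
    """Static description of one meteorological station."""

    station_id: str
    name: str
    latitude: float  # decimal degrees, positive north
    longitude: float  # decimal degrees, positive east
    elevation: float  # m a.s.l.
    variety: str  # crop parameter-set key planted in the station's region

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.elevation < 0:
            raise ValueError(f"elevation {self.elevation} must be >= 0")


@dataclass(frozen=True)
class SeasonalSummary:
    """Growing-season climate aggregates for one station-year.

    ``eat`` is the effective accumulated temperature, the base-0 sum of daily
    mean temperature over the window (°C·day); ``ra_total`` is the seasonal
    radiation total in MJ/m²; ``annual_at0`` is the base-0 accumulated
    temperature over the full calendar year, the quantity used to stratify
    stations into temperature zones.
    """

    station_id: str
    year: int
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    tave: float
    tmax: float
    tmin: float
    tdr: float
    eat: float
    ra_total: float
    annual_at0: float


def extraterrestrial_radiation(latitude, day_of_year):
    """Extraterrestrial radiation and astronomical daylength for one day.

    Uses the FAO-56 astronomical formulas: solar declination and the inverse
    relative Earth–Sun distance from the day-of-year, the sunset hour angle
    from latitude and declination, daylength ``N = 24 ωs / π``.

    Parameters
    ----------
    latitude : float
        Decimal degrees, positive north.
    day_of_year : int or array of int
        1..366.

    Returns
    -------
    (Ra_max, N)
        Daily extraterrestrial radiation in kJ/m²/day and daylength in hours
        (scalars for scalar input, arrays otherwise).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    j = np.asarray(day_of_year, dtype=float)
    if np.any(j < 1) or np.any(j > 366):
        raise ValueError("day_of_year outside [1, 366]")

    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    # clip handles polar day (x < -1) and polar night (x > 1)
    ws = np.arccos(np.clip(-math.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * _GSC_KJ_MIN * dr * (
        ws * math.sin(phi) * np.sin(delta)
        + math.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    ra = np.maximum(ra, 0.0)
    daylength = 24.0 * ws / np.pi
    if np.isscalar(day_of_year) or np.ndim(day_of_year) == 0:
        return float(ra), float(daylength)
    return ra, daylength


def angstrom_radiation(
    n: float,
    big_n: float,
    ra_max: float,
    a: float = ANGSTROM_A,
    b: float = ANGSTROM_B,
) -> float:
    """Global solar radiation from relative sunshine duration.

    ``Ra = Ra_max · [a + b·(n/N)]`` with the plateau coefficients
    a = 0.27, b = 0.55 by default.  With zero daylength (polar night) the
    overcast limit ``a·Ra_max`` is returned; sunshine reported during polar
    night is a data error.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Angstrom coefficients must be positive")
    if n < 0:
        raise ValueError(f"negative sunshine duration {n}")
    if big_n == 0.0:
        if n > 0:
            raise ValueError("sunshine hours reported with zero daylength")
        return a * ra_max
    if n > big_n + 1e-9:
        raise ValueError(f"sunshine {n} h exceeds daylength {big_n} h")
    return ra_max * (a + b * (n / big_n))


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapour pressure (kPa) at air temperature ``t`` (°C).

    Tetens curve, ``0.6108·exp(17.27·T / (T + 237.3))``.
    """
    if not -60.0 <= t <= 60.0:
        raise ValueError(f"temperature {t} °C outside plausible range")
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def actual_vapor_pressure(rh_mean: float, tx: float, tn: float) -> float:
    """Actual vapour pressure (kPa) from mean relative humidity.

    ``ea = (RHmean/100) · (e⁰(Tmax) + e⁰(Tmin)) / 2``.
    """
    if not 0.0 <= rh_mean <= 100.0:
        raise ValueError(f"relative humidity {rh_mean}% outside [0, 100]")
    if tn > tx:
        raise ValueError(f"Tmin {tn} exceeds Tmax {tx}")
    return (rh_mean / 100.0) * 0.5 * (
        saturation_vapor_pressure(tx) + saturation_vapor_pressure(tn)
    )


def wind_at_2m(v_h: float, z: float = 2.0, z_h: float = 10.0) -> float:
    """Rescale wind speed from measurement height ``z_h`` to height ``z``.

    Power-law profile ``V = V_H · (Z/Z_H)^0.16``.
    """
    if np.any(np.asarray(v_h) < 0):
        raise ValueError("negative wind speed")
    return v_h * (z / z_h) ** WIND_PROFILE_ALPHA


# ---------------------------------------------------------------------------
# Frame-level derivation

RAW_COLUMNS = [
    "station_id", "date", "tave", "tmax", "tmin",
    "sunshine_h", "wind10", "rh", "precip",
]


def derive_daily(raw: pd.DataFrame, meta: StationMeta) -> pd.DataFrame:
    """Derive the simulation-ready quantities for each station-day.

    Adds ``tdr`` (diurnal range), ``ra_max`` and ``daylength`` (astronomical),
    ``ra`` (Angstrom–Prescott global radiation, kJ/m²/day), ``ea`` (actual
    vapour pressure, kPa) and ``wind2`` (2-m wind).  A missing ``tave`` is
    imputed as ``(tmax + tmin)/2``.  Rows whose remaining required fields are
    missing or violate physical ordering are dropped with a logged count.
    """
    df = raw.copy()
    df["date"] = pd.to_datetime(df["date"])

    imputable = df["tave"].isna() & df["tmax"].notna() & df["tmin"].notna()
    df.loc[imputable, "tave"] = 0.5 * (df.loc[imputable, "tmax"] + df.loc[imputable, "tmin"])

    required = ["tave", "tmax", "tmin", "sunshine_h", "wind10", "rh"]
    ok = df[required].notna().all(axis=1)
    ok &= df["tmin"] <= df["tmax"]
    ok &= (df["rh"] >= 0) & (df["rh"] <= 100)
    ok &= df["sunshine_h"] >= 0
    ok &= df["wind10"] >= 0
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("station %s: dropped %d unusable daily records", meta.station_id, n_bad)
        df = df[ok]

    doy = df["date"].dt.dayofyear.to_numpy()
    ra_max, daylength = extraterrestrial_radiation(meta.latitude, doy)
    df["ra_max"] = ra_max
    df["daylength"] = daylength
    sun = np.minimum(df["sunshine_h"].to_numpy(), daylength)
    df["ra"] = ra_max * (ANGSTROM_A + ANGSTROM_B * sun / daylength)
    df["tdr"] = df["tmax"] - df["tmin"]

    def _tetens(t: np.ndarray) -> np.ndarray:
        return 0.6108 * np.exp(17.27 * t / (t + 237.3))

    df["ea"] = (df["rh"].to_numpy() / 100.0) * 0.5 * (
        _tetens(df["tmax"].to_numpy()) + _tetens(df["tmin"].to_numpy())
    )
    df["wind2"] = wind_at_2m(df["wind10"].to_numpy())
    return df.reset_index(drop=True)


def seasonal_summary(
    daily: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    station_id: str | None = None,
) -> SeasonalSummary:
    """Aggregate a derived daily series over a growing-season window.

    Means of Tave/Tmax/Tmin/TDR over the (inclusive) window, effective
    accumulated temperature ``EAT = Σ max(Tave, 0)``, seasonal radiation
    total in MJ/m², and the base-0 accumulated temperature over the whole
    calendar year of the window start.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        raise ValueError("empty seasonal window")
    if "tdr" not in daily.columns:
        daily = daily.assign(tdr=daily["tmax"] - daily["tmin"])
    d = daily["date"]
    in_win = daily[(d >= start) & (d <= end)]
    if in_win.empty:
        raise ValueError(f"no records inside window {start.date()}..{end.date()}")
    year = int(start.year)
    in_year = daily[d.dt.year == year]
    sid = station_id or str(in_win["station_id"].iloc[0])
    return SeasonalSummary(
        station_id=sid,
        year=year,
        window_start=start,
        window_end=end,
        tave=float(in_win["tave"].mean()),
        tmax=float(in_win["tmax"].mean()),
        tmin=float(in_win["tmin"].mean()),
        tdr=float(in_win["tdr"].mean()),
        eat=float(np.maximum(in_win["tave"], 0.0).sum()),
        ra_total=float(in_win["ra"].sum()) * 1e-3,
        annual_at0=float(np.maximum(in_year["tave"], 0.0).sum()),
    )


# ---------------------------------------------------------------------------
# File formats

def read_station_csv(path: str | Path) -> pd.DataFrame:
    """Read the raw per-station-day delimited file."""
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station file {path} missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_station_meta(path: str | Path) -> dict[str, StationMeta]:
    """Read the station metadata table into a dict keyed by station id."""
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.station_id)] = StationMeta(
            station_id=str(row.station_id), name=str(row.name),
            latitude=float(row.lat), longitude=float(row.lon),
            elevation=float(row.elev), variety=str(row.variety),
        )
    return out


_CABO_COLS = ["station", "year", "doy", "irrad_kj", "tmin", "tmax", "vap_kpa", "wind2", "precip"]


def write_cabo_weather(daily: pd.DataFrame, station_id: str, path: str | Path) -> None:
    """Write a derived daily frame as a CABO-style simulation weather file.

    One whitespace-delimited row per day: station, year, day-of-year,
    irradiation (kJ/m²/day), Tmin, Tmax (°C), vapour pressure (kPa),
    2-m wind (m/s), precipitation (mm).
    """
    out = pd.DataFrame({
        "station": station_id,
        "year": daily["date"].dt.year,
        "doy": daily["date"].dt.dayofyear,
        "irrad_kj": daily["ra"].round(1),
        "tmin": daily["tmin"].round(2),
        "tmax": daily["tmax"].round(2),
        "vap_kpa": daily["ea"].round(4),
        "wind2": daily["wind2"].round(3),
        "precip": daily["precip"].round(2),
    })
    with open(path, "w") as fh:
        fh.write("* " + " ".join(_CABO_COLS) + "\n")
        out.to_csv(fh, sep=" ", header=False, index=False)


def read_cabo_weather(path: str | Path) -> pd.DataFrame:
    """Read a CABO-style weather file written by :func:`write_cabo_weather`."""
    df = pd.read_csv(path, sep=r"\s+", comment="*", names=_CABO_COLS)
    df["tave"] = 0.5 * (df["tmin"] + df["tmax"])
    df["date"] = pd.to_datetime(df["year"] * 1000 + df["doy"], format="%Y%j")
    return df
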