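"""Synthetic alpine station-weather archives and yield-climate panels.

The weather generator emulates multi-decade daily records of
high-plateau stations: a station-specific seasonal temperature cycle tied to
elevation, correlated AR(1) day-to-day anomalies of Tmax and Tmin, a
seasonal sunshine-fraction process, and configurable linear trends — by
default a warming of 0.33 (Tmax) and 0.47 °C per decade (Tmin) and a slight
sunshine decline, the magnitudes characteristic of the plateau's recent
four decades.  Defaults are chosen so growing-season means land inside the
observed plateau climatology (season Tave roughly 10–19 °C, effective
accumulated temperature 1400–2700 °C·day, seasonal radiation total
2400–3700 MJ/m²).

The panel generator draws first-difference climate predictors from a
configurable covariance and builds Δ-yield as a known linear combination
plus noise, providing ground truth for the attribution stage.

Everything is reproducible from (config, seed): the same configuration
yields byte-identical archives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import PREDICTORS

__all__ = ["WeatherGenConfig", "PanelGenConfig", "gen_station_weather", "gen_yield_panel"]

_VARIETIES = ("Chaiqing-1", "Zangqing-2000", "Diqing-1")


@dataclass(frozen=True)
class WeatherGenConfig:
    """Configuration of the synthetic station-weather generator."""

    seed: int
    n_stations: int = 50
    year_start: int = 1978
    year_end: int = 2017
    latitude_range: tuple[float, float] = (28.0, 38.0)
    longitude_range: tuple[float, float] = (80.0, 102.0)
    elevation_range: tuple[float, float] = (2300.0, 4500.0)
    # seasonal cycle of daily mean temperature: annual mean from a lapse
    # relation against elevation, cosine harmonic peaking mid-summer
    sea_level_mean: float = 16.5        # °C intercept of the lapse relation
    lapse_rate: float = 0.0033          # °C per m elevation
    temp_amplitude_range: tuple[float, float] = (9.5, 12.0)
    peak_doy: float = 200.0
    # mean diurnal range (°C) and its station-to-station spread
    tdr_mean_range: tuple[float, float] = (10.0, 14.5)
    # AR(1) anomalies of (Tmax, Tmin)
    ar1_phi: float = 0.65
    sigma_tmax: float = 1.9
    sigma_tmin: float = 1.6
    anomaly_correlation: float = 0.7
    # imposed linear trends, °C per decade
    trend_tmax: float = 0.33
    trend_tmin: float = 0.47
    # sunshine fraction process and its trend (fraction per decade).  The
    # station-mean sunshine fraction is coupled to station warmth: the cool
    # eastern margin of the emulated region sits under the summer monsoon
    # cloud band while the warm cropping valleys are sunny, so cloudiness
    # decreases with annual mean temperature.
    sun_base: float = 0.48              # sunshine fraction at a 4 °C station
    sun_temp_coupling: float = 0.07     # d(sun fraction)/d(annual mean °C)
    sun_bounds: tuple[float, float] = (0.25, 0.68)
    sun_amplitude: float = 0.10
    sun_sigma: float = 0.15
    trend_sun: float = -0.005
    # humidity and wind
    rh_mean: float = 52.0
    rh_amplitude: float = 14.0
    rh_sigma: float = 8.0
    wind_mean: float = 2.0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if min(self.sigma_tmax, self.sigma_tmin) <= 0:
            raise ValueError("anomaly standard deviations must be positive")
        if self.year_end < self.year_start:
            raise ValueError("degenerate year range")


def _ar1_bivariate(rng, n, phi, s1, s2, rho):
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]) * (1 - phi**2)
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    out = np.empty((n, 2))
    out[0] = rng.multivariate_normal([0.0, 0.0], cov / (1 - phi**2), method="cholesky")
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def gen_station_weather(config: WeatherGenConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic multi-station daily archive.

    Returns ``(meta, daily)``: the station-metadata table (station_id, name,
    lat, lon, elev, variety) and the raw daily table in the preprocessing
    input schema (station_id, date, tave, tmax, tmin, sunshine_h, wind10,
    rh, precip).
    """
    root = np.random.SeedSequence(config.seed)
    station_seeds = root.spawn(config.n_stations)

    dates = pd.date_range(
        f"{config.year_start}-01-01", f"{config.year_end}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    years_from_start = (np.arange(n) / 365.25)
    season = np.cos(2.0 * np.pi * (doy - config.peak_doy) / 365.25)

    meta_rows, daily_frames = [], []
    for k, seed in enumerate(station_seeds):
        rng = np.random.default_rng(seed)
        sid = f"SYN{k:03d}"
        lat = rng.uniform(*config.latitude_range)
        lon = rng.uniform(*config.longitude_range)
        elev = rng.uniform(*config.elevation_range)
        variety = _VARIETIES[k % len(_VARIETIES)]
        meta_rows.append({
            "station_id": sid, "name": f"synthetic-{k:03d}", "lat": round(lat, 3),
            "lon": round(lon, 3), "elev": round(elev, 0), "variety": variety,
        })

        tmean = config.sea_level_mean - config.lapse_rate * elev + rng.normal(0.0, 0.6)
        amp = rng.uniform(*config.temp_amplitude_range)
        tdr0 = rng.uniform(*config.tdr_mean_range)
        tcycle = tmean + amp * season

        anom = _ar1_bivariate(
            rng, n, config.ar1_phi, config.sigma_tmax, config.sigma_tmin,
            config.anomaly_correlation,
        )
        tmax = (
            tcycle + 0.5 * tdr0 + anom[:, 0]
            + config.trend_tmax * years_from_start / 10.0
        )
        tmin = (
            tcycle - 0.5 * tdr0 + anom[:, 1]
            + config.trend_tmin * years_from_start / 10.0
        )
        # repair the rare draws that invert the diurnal ordering
        swap = tmin > tmax
        tmax[swap], tmin[swap] = tmin[swap].copy(), tmax[swap].copy()
        tave = 0.5 * (tmax + tmin)

        sun_mean = float(np.clip(
            config.sun_base + config.sun_temp_coupling * (tmean - 4.0),
            *config.sun_bounds,
        ))
        sun = (
            sun_mean
            + config.sun_amplitude * np.cos(2.0 * np.pi * (doy - 340.0) / 365.25)
            + config.trend_sun * years_from_start / 10.0
            + rng.normal(0.0, config.sun_sigma, size=n)
        )
        sun = np.clip(sun, 0.0, 1.0)
        # astronomical daylength bound is applied downstream; store hours
        # against a nominal 13-h midsummer day scaled by season
        daylength_nominal = 12.0 + 1.8 * season
        sunshine_h = sun * daylength_nominal

        rh = np.clip(
            config.rh_mean + config.rh_amplitude * season + rng.normal(0.0, config.rh_sigma, n),
            3.0, 100.0,
        )
        wind10 = rng.gamma(shape=4.0, scale=config.wind_mean / 4.0, size=n)
        wet = rng.random(n) < np.clip(0.15 + 0.25 * season, 0.02, 0.45)
        precip = np.where(wet, rng.gamma(1.2, 4.0, size=n), 0.0)

        daily_frames.append(pd.DataFrame({
            "station_id": sid,
            "date": dates,
            "tave": np.round(tave, 2),
            "tmax": np.round(tmax, 2),
            "tmin": np.round(tmin, 2),
            "sunshine_h": np.round(sunshine_h, 2),
            "wind10": np.round(wind10, 2),
            "rh": np.round(rh, 1),
            "precip": np.round(precip, 2),
        }))

    return pd.DataFrame(meta_rows), pd.concat(daily_frames, ignore_index=True)


@dataclass(frozen=True)
class PanelGenConfig:
    """Configuration of the synthetic first-difference yield-climate panel."""

    seed: int
    n_rows: int = 500
    #: true Δ-yield response per unit of each Δ-predictor (kg/ha per unit)
    coefficients: dict = field(default_factory=lambda: {"dRA": 2.34})
    intercept: float = 0.0
    noise_sigma: float = 50.0
    #: marginal standard deviations of the Δ-predictors
    predictor_sigma: dict = field(default_factory=lambda: {
        "dTave": 0.6, "dTmax": 0.7, "dTmin": 0.6, "dEAT": 80.0, "dTDR": 0.5, "dRA": 150.0,
    })
    #: pairwise correlation applied between all predictor pairs
    predictor_correlation: float = 0.2

    def __post_init__(self) -> None:
        if self.n_rows < 10:
            raise ValueError("panel needs at least 10 rows")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not -1.0 / (len(PREDICTORS) - 1) < self.predictor_correlation < 1.0:
            raise ValueError("predictor correlation gives a non-positive-definite covariance")


def gen_yield_panel(config: PanelGenConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a zone panel with known ground truth.

    Returns ``(panel, truth)`` where the panel has columns dYp plus the six
    Δ-predictors and ``truth`` records the generating coefficients,
    intercept and noise level.
    """
    rng = np.random.default_rng(config.seed)
    k = len(PREDICTORS)
    sig = np.array([config.predictor_sigma[p] for p in PREDICTORS])
    corr = np.full((k, k), config.predictor_correlation)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sig, sig)
    try:
        x = rng.multivariate_normal(np.zeros(k), cov, size=config.n_rows, method="cholesky")
    except np.linalg.LinAlgError as exc:
        raise ValueError("predictor covariance is not positive definite") from exc
    beta = np.array([config.coefficients.get(p, 0.0) for p in PREDICTORS])
    y = config.intercept + x @ beta + rng.normal(0.0, config.noise_sigma, config.n_rows)
    panel = pd.DataFrame(x, columns=PREDICTORS)
    panel.insert(0, "dYp", y)
    truth = {
        "coefficients": dict(config.coefficients),
        "intercept": config.intercept,
        "noise_sigma": config.noise_sigma,
    }
    return panel, truth
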