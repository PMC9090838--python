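"""End-to-end pipeline: synthesize → preprocess → simulate → trends → attribute.

Each stage reads and writes plain delimited tables under the run directory,
so any stage can equally be driven by external data with the same schema.
A JSON manifest records the configuration, seed, package version and a
checksum of every stage output; re-running with the same configuration
reproduces the manifest bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .attribution import build_zone_panels, pearson_matrix, stepwise_mlr
from .crop import simulate_station_years
from .synth import WeatherGenConfig, gen_station_weather
from .trends import trend_table
from .weather import (
    derive_daily,
    read_cabo_weather,
    read_station_csv,
    read_station_meta,
    seasonal_summary,
    write_cabo_weather,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

CLIMATE_VARS = ["tave", "tmax", "tmin", "tdr", "eat", "ra_total"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    n_stations: int = 50
    year_start: int = 1978
    year_end: int = 2017
    trend_mode: str = "tie_adjusted"       # or "as_printed"
    p_enter: float = 0.05
    p_remove: float = 0.10
    include_immature: bool = False          # keep season_end runs in statistics
    weather_overrides: dict = field(default_factory=dict)

    def weather_config(self) -> WeatherGenConfig:
        return WeatherGenConfig(
            seed=self.seed, n_stations=self.n_stations,
            year_start=self.year_start, year_end=self.year_end,
            **self.weather_overrides,
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def stage_synth(cfg: RunConfig) -> tuple[Path, Path]:
    """Generate the raw synthetic archive (meta + daily observations)."""
    raw = Path(cfg.out_dir) / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    meta, daily = gen_station_weather(cfg.weather_config())
    meta_path, daily_path = raw / "stations_meta.csv", raw / "daily.csv"
    meta.to_csv(meta_path, index=False)
    daily.to_csv(daily_path, index=False)
    return meta_path, daily_path


def stage_preprocess(cfg: RunConfig, meta_path: Path, daily_path: Path) -> Path:
    """Derive radiation/vapour-pressure/wind quantities; write CABO files."""
    out = Path(cfg.out_dir) / "weather"
    out.mkdir(parents=True, exist_ok=True)
    metas = read_station_meta(meta_path)
    daily = read_station_csv(daily_path)
    for sid, grp in daily.groupby("station_id"):
        derived = derive_daily(grp, metas[str(sid)])
        write_cabo_weather(derived, str(sid), out / f"{sid}.wth")
    return out


def stage_simulate(cfg: RunConfig, meta_path: Path, weather_dir: Path) -> Path:
    """Run the potential-production simulator for every station-year."""
    metas = read_station_meta(meta_path)
    frames = []
    for sid, meta in metas.items():
        w = read_cabo_weather(Path(weather_dir) / f"{sid}.wth")
        w = w.rename(columns={"irrad_kj": "ra"})
        frames.append(
            simulate_station_years(w, meta.variety, sid, latitude=meta.latitude)
        )
    table = pd.concat(frames, ignore_index=True)
    path = Path(cfg.out_dir) / "station_years.csv"
    table.to_csv(path, index=False)
    return path


def stage_seasonal(cfg: RunConfig, meta_path: Path, weather_dir: Path, sim_path: Path) -> Path:
    """Growing-season climate summaries on the simulated phenological window.

    The window is [sowing, maturity]; runs that never matured fall back to
    [sowing, 30 September].
    """
    metas = read_station_meta(meta_path)
    sims = pd.read_csv(sim_path)
    rows = []
    for sid, meta in metas.items():
        w = read_cabo_weather(Path(weather_dir) / f"{sid}.wth")
        w = w.rename(columns={"irrad_kj": "ra"})
        w["tdr"] = w["tmax"] - w["tmin"]
        for rec in sims[sims["station_id"] == sid].itertuples(index=False):
            sow = pd.Timestamp(rec.sowing)
            if isinstance(rec.maturity, str) and rec.maturity:
                end = pd.Timestamp(rec.maturity)
            else:
                end = pd.Timestamp(year=int(rec.year), month=9, day=30)
            summ = seasonal_summary(w, (sow, end), station_id=sid)
            rows.append({
                "station_id": sid, "year": int(rec.year),
                "tave": summ.tave, "tmax": summ.tmax, "tmin": summ.tmin,
                "tdr": summ.tdr, "eat": summ.eat, "ra_total": summ.ra_total,
                "annual_at0": summ.annual_at0,
            })
    path = Path(cfg.out_dir) / "seasonal.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _joined_station_years(cfg: RunConfig, sim_path: Path, seasonal_path: Path) -> pd.DataFrame:
    sims = pd.read_csv(sim_path)
    seas = pd.read_csv(seasonal_path)
    df = sims.merge(seas, on=["station_id", "year"])
    if not cfg.include_immature:
        n_drop = int((df["termination_reason"] != "maturity").sum())
        if n_drop:
            log.info("excluding %d station-years that did not reach maturity", n_drop)
        df = df[df["termination_reason"] == "maturity"]
    return df


def stage_trends(cfg: RunConfig, sim_path: Path, seasonal_path: Path) -> Path:
    """Mann–Kendall + Sen's slope per station for yield and climate factors."""
    df = _joined_station_years(cfg, sim_path, seasonal_path)
    tidy = df.melt(
        id_vars=["station_id", "year"],
        value_vars=["yield_kg_ha"] + CLIMATE_VARS,
        var_name="variable", value_name="value",
    )
    out = trend_table(tidy, mode=cfg.trend_mode)
    path = Path(cfg.out_dir) / "trends.csv"
    out.to_csv(path, index=False)
    return path


def stage_attribute(cfg: RunConfig, sim_path: Path, seasonal_path: Path) -> tuple[Path, Path]:
    """Zone-stratified first-difference correlation and stepwise regression."""
    df = _joined_station_years(cfg, sim_path, seasonal_path)
    panels = build_zone_panels(df)
    corr_rows, reg_rows = [], []
    for zone, panel in panels.items():
        if len(panel) >= 3:
            c = pearson_matrix(panel)
            c.insert(0, "zone", zone)
            corr_rows.append(c)
        if len(panel) >= 10:
            r = stepwise_mlr(panel, p_enter=cfg.p_enter, p_remove=cfg.p_remove, zone=zone)
            reg_rows.append({
                "zone": zone, "equation": r.equation(), "F": r.f_statistic,
                "sig": r.p_value, "R2": r.r2, "RMSE": r.rmse, "n": r.n,
            })
    corr_path = Path(cfg.out_dir) / "correlations.csv"
    reg_path = Path(cfg.out_dir) / "regressions.csv"
    pd.concat(corr_rows, ignore_index=True).to_csv(corr_path, index=False)
    pd.DataFrame(reg_rows).to_csv(reg_path, index=False)
    return corr_path, reg_path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the manifest; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}

    stage = "synth"
    try:
        meta_path, daily_path = stage_synth(cfg)
        artefacts["stations_meta"], artefacts["daily"] = meta_path, daily_path
        stage = "preprocess"
        weather_dir = stage_preprocess(cfg, meta_path, daily_path)
        for p in sorted(weather_dir.glob("*.wth")):
            artefacts[f"weather/{p.name}"] = p
        stage = "simulate"
        sim_path = stage_simulate(cfg, meta_path, weather_dir)
        artefacts["station_years"] = sim_path
        stage = "seasonal"
        seasonal_path = stage_seasonal(cfg, meta_path, weather_dir, sim_path)
        artefacts["seasonal"] = seasonal_path
        stage = "trends"
        artefacts["trends"] = stage_trends(cfg, sim_path, seasonal_path)
        stage = "attribute"
        corr_path, reg_path = stage_attribute(cfg, sim_path, seasonal_path)
        artefacts["correlations"], artefacts["regressions"] = corr_path, reg_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["out_dir"] = str(cfg.out_dir)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "outputs": {k: _checksum(p) for k, p in sorted(artefacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
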