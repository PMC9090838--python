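"""TSUM calibration from phenology records and simulation-accuracy metrics.

Thermal-time requirements for each phenological phase are the base-0 sums of
daily mean temperature over half-open phase intervals ``[start, end)`` — the
transition day's temperature counts toward the new phase exactly once.
Simulated output is scored against observations with five metrics: Pearson
r, its square R², root mean square error, relative RMSE (% of the observed
mean) and the percentage deviation coefficient
``PDC = Σ(obs − sim) / Σ obs · 100%``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PhenologyRecord", "ValidationReport", "derive_tsum", "validation_metrics", "read_phenology"]


@dataclass(frozen=True)
class PhenologyRecord:
    """Observed phenology (and optionally yield) for one station-year trial."""

    station_id: str
    year: int
    sown_date: pd.Timestamp
    emergence_date: pd.Timestamp | None
    maturity_date: pd.Timestamp | None
    anthesis_date: pd.Timestamp | None = None
    observed_yield: float | None = None
    observed_duration: int | None = None

    def __post_init__(self) -> None:
        seq = [d for d in (self.sown_date, self.emergence_date,
                           self.anthesis_date, self.maturity_date) if d is not None]
        if any(a > b for a, b in zip(seq, seq[1:])):
            raise ValueError("phenology dates out of order")
        if self.observed_yield is not None and self.observed_yield <= 0:
            raise ValueError("observed yield must be positive")


@dataclass(frozen=True)
class ValidationReport:
    """Agreement between observed and simulated values."""

    n: int
    r: float       # Pearson correlation (NaN when either side is constant)
    r2: float
    rmse: float    # units of the compared quantity
    rrmse: float   # % of the observed mean
    pdc: float     # %


def _phase_tsum(daily: pd.DataFrame, start, end) -> float | None:
    """Base-0 thermal time over the half-open interval [start, end)."""
    if start is None or end is None:
        return None
    d = daily["date"]
    phase = daily[(d >= pd.Timestamp(start)) & (d < pd.Timestamp(end))]
    return float(np.maximum(phase["tave"], 0.0).sum())


def derive_tsum(
    daily: pd.DataFrame, record: PhenologyRecord, round_to_50: bool = False
) -> tuple[float | None, float | None, float | None]:
    """Thermal-time requirements (sowing→emergence, →anthesis, →maturity).

    Each phase with a missing boundary date is returned as None.  With
    ``round_to_50`` the values are rounded to the nearest 50 °C·day, the
    granularity customary for variety parameter files.
    """
    t_em = _phase_tsum(daily, record.sown_date, record.emergence_date)
    t1 = _phase_tsum(daily, record.emergence_date, record.anthesis_date)
    t2 = _phase_tsum(daily, record.anthesis_date, record.maturity_date)
    if record.anthesis_date is None:
        # only the emergence→maturity total is identifiable
        t1 = _phase_tsum(daily, record.emergence_date, record.maturity_date)
        t2 = None
    if round_to_50:
        rnd = lambda v: None if v is None else 50.0 * round(v / 50.0)
        t_em, t1, t2 = rnd(t_em), rnd(t1), rnd(t2)
    return t_em, t1, t2


def validation_metrics(observed, simulated) -> ValidationReport:
    """Score simulated against observed values with the five-metric report."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("observed and simulated must have equal length")
    n = obs.size
    if n < 2:
        raise ValueError("need at least two pairs")
    mean_obs = obs.mean()
    if mean_obs == 0:
        raise ValueError("observed mean is zero; RRMSE undefined")
    do = obs - mean_obs
    ds = sim - sim.mean()
    denom = np.sqrt((do**2).sum() * (ds**2).sum())
    r = float((do * ds).sum() / denom) if denom > 0 else float("nan")
    rmse = float(np.sqrt(((obs - sim) ** 2).mean()))
    return ValidationReport(
        n=n,
        r=r,
        r2=r * r if np.isfinite(r) else float("nan"),
        rmse=rmse,
        rrmse=100.0 * rmse / mean_obs,
        pdc=100.0 * float((obs - sim).sum() / obs.sum()),
    )


def read_phenology(path: str | Path) -> list[PhenologyRecord]:
    """Read a delimited phenology-trial table.

    Columns: station_id, year, sown_date, emergence_date, anthesis_date,
    maturity_date, observed_yield, observed_duration (dates ISO-8601, blank
    where unobserved).
    """
    df = pd.read_csv(path)
    recs = []
    for row in df.itertuples(index=False):
        def _date(v):
            return None if pd.isna(v) or v == "" else pd.Timestamp(v)
        recs.append(PhenologyRecord(
            station_id=str(row.station_id),
            year=int(row.year),
            sown_date=pd.Timestamp(row.sown_date),
            emergence_date=_date(row.emergence_date),
            anthesis_date=_date(getattr(row, "anthesis_date", None)),
            maturity_date=_date(row.maturity_date),
            observed_yield=None if pd.isna(row.observed_yield) else float(row.observed_yield),
            observed_duration=None if pd.isna(row.observed_duration) else int(row.observed_duration),
        ))
    return recs
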