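"""Variety parameter sets for the potential-production barley simulator.

Phenology is driven by thermal-time requirements (TSUMs, base 0 °C) calibrated
per variety for the three phases sowing→emergence, emergence→anthesis and
anthesis→maturity.  Physiology follows the standard potential-production
formulation for spring barley: light-saturated leaf assimilation AMAX with a
temperature response, initial light-use efficiency EFF, diffuse extinction
KDIF, organ-specific assimilate conversion efficiencies, Q10 maintenance
respiration, and development-stage-indexed dry-matter partitioning.

Partitioning is stored as the root fraction of total assimilate (``frtb``)
plus leaf and storage-organ fractions of the shoot share (``fltb``,
``fotb``); the stem fraction is the shoot complement, so the three shoot
fractions sum to one by construction at every development stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CropParameterSet", "PARAMETER_SETS", "SOWING_DATE", "get_params"]


def _interp(dvs: float, table: tuple[tuple[float, float], ...]) -> float:
    xs = [p[0] for p in table]
    ys = [p[1] for p in table]
    return float(np.interp(dvs, xs, ys))


@dataclass(frozen=True)
class CropParameterSet:
    """Full parameter set for one highland-barley variety."""

    variety: str
    # thermal-time requirements, °C·day above base 0
    tsum_em: float    # sowing → emergence
    tsum1: float      # emergence → anthesis
    tsum2: float      # anthesis → maturity
    # assimilation
    amax: float = 35.0          # max leaf CO2 assimilation, kg CO2/ha/h
    eff: float = 0.45           # initial light-use efficiency, kg CO2/ha/h per J/m2/s
    kdif: float = 0.60          # extinction coefficient for diffuse light
    canopy_reflection: float = 0.08
    # temperature response of AMAX, daytime temperature (°C) -> multiplier
    tmpftb: tuple[tuple[float, float], ...] = (
        (-10.0, 0.01), (0.0, 0.01), (10.0, 0.60), (15.0, 1.0), (25.0, 1.0), (35.0, 0.01),
    )
    # development-stage response of AMAX: in barley, photosynthetic capacity
    # declines from anthesis onward as the flag leaf and ear age (full
    # capacity to DVS 1.0, ~63% at 1.3, ~22% at maturity)
    amaxtb_dvs: tuple[tuple[float, float], ...] = (
        (0.0, 1.0), (1.0, 1.0), (1.3, 0.625), (2.0, 0.218),
    )
    # cold-night reduction of gross assimilation: multiplier as a function
    # of the 7-day running mean of daily minimum temperature (°C)
    tmnftb: tuple[tuple[float, float], ...] = ((-5.0, 0.0), (3.0, 1.0))
    # maintenance respiration, kg CH2O per kg dry matter per day at Tref
    rml: float = 0.03
    rms: float = 0.015
    rmo: float = 0.01
    rmr: float = 0.01
    q10: float = 2.0
    tref: float = 25.0          # reference temperature for Q10 scaling, °C
    # assimilate conversion efficiencies, kg dry matter per kg CH2O
    cvl: float = 0.685
    cvs: float = 0.662
    cvo: float = 0.709
    cvr: float = 0.694
    # leaf dynamics
    span: float = 25.0          # leaf life span at 35 °C, days
    rgrlai: float = 0.0075      # max relative LAI growth rate, ha/ha per °C·day
    perdl: float = 0.02         # max relative leaf death rate (unused at potential level)
    sla: float = 0.0022         # specific leaf area, ha/kg
    laicr: float = 4.0          # critical LAI for self-shading mortality
    tdwi: float = 120.0         # initial total crop dry weight at emergence, kg/ha
    # partitioning: root fraction of total assimilate vs DVS
    frtb: tuple[tuple[float, float], ...] = (
        (0.00, 0.50), (0.10, 0.43), (0.20, 0.36), (0.35, 0.22), (0.40, 0.17),
        (0.50, 0.13), (0.70, 0.07), (0.90, 0.03), (1.20, 0.00), (2.00, 0.00),
    )
    # leaf / storage-organ fractions of the shoot share vs DVS
    fltb: tuple[tuple[float, float], ...] = (
        (0.00, 0.65), (0.25, 0.70), (0.50, 0.50), (0.65, 0.30), (0.95, 0.00), (2.00, 0.00),
    )
    fotb: tuple[tuple[float, float], ...] = (
        (0.00, 0.00), (0.90, 0.00), (0.95, 0.50), (1.00, 0.80), (1.05, 1.00), (2.00, 1.00),
    )

    def __post_init__(self) -> None:
        if min(self.tsum_em, self.tsum1, self.tsum2) <= 0:
            raise ValueError("all TSUMs must be positive")
        for dvs in np.linspace(0.0, 2.0, 201):
            fl, fs, fo = self.shoot_fractions(float(dvs))
            if min(fl, fs, fo) < -1e-12:
                raise ValueError(f"negative shoot partition fraction at DVS={dvs:.2f}")

    # -- derived lookups ----------------------------------------------------
    def root_fraction(self, dvs: float) -> float:
        return _interp(dvs, self.frtb)

    def shoot_fractions(self, dvs: float) -> tuple[float, float, float]:
        """(leaf, stem, storage) fractions of the shoot assimilate share."""
        fl = _interp(dvs, self.fltb)
        fo = _interp(dvs, self.fotb)
        return fl, 1.0 - fl - fo, fo

    def amax_at(self, daytime_temp: float, dvs: float = 0.0) -> float:
        return (
            self.amax
            * _interp(daytime_temp, self.tmpftb)
            * _interp(dvs, self.amaxtb_dvs)
        )

    def cold_night_factor(self, tmin_week: float) -> float:
        """Gross-assimilation multiplier after cold nights.

        ``tmin_week`` is the running 7-day mean of daily minimum temperature.
        """
        return _interp(tmin_week, self.tmnftb)


#: Thermal-time calibration per variety (°C·day; base 0 °C).
PARAMETER_SETS: dict[str, CropParameterSet] = {
    "Chaiqing-1": CropParameterSet("Chaiqing-1", tsum_em=100.0, tsum1=650.0, tsum2=850.0),
    "Zangqing-2000": CropParameterSet("Zangqing-2000", tsum_em=100.0, tsum1=700.0, tsum2=950.0),
    "Diqing-1": CropParameterSet("Diqing-1", tsum_em=100.0, tsum1=800.0, tsum2=1050.0),
}

#: Conventional sowing date (month, day) per variety: 10, 20 and 30 April.
SOWING_DATE: dict[str, tuple[int, int]] = {
    "Chaiqing-1": (4, 10),
    "Zangqing-2000": (4, 20),
    "Diqing-1": (4, 30),
}


def get_params(variety: str, **overrides) -> CropParameterSet:
    """Return the parameter set for ``variety``, optionally overridden."""
    try:
        base = PARAMETER_SETS[variety]
    except KeyError:
        raise KeyError(
            f"unknown variety {variety!r}; known: {sorted(PARAMETER_SETS)}"
        ) from None
    return replace(base, **overrides) if overrides else base
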