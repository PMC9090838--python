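"""Daily-timestep potential-production crop growth simulator.

The model simulates the yield a barley crop can reach when water and
nutrients are non-limiting, so growth is driven only by incoming solar
radiation, temperature and the crop's own traits:

* **Phenology** — development runs on thermal time above a 0 °C base.
  Emergence fires when the post-sowing sum reaches ``tsum_em``; the
  development stage DVS then advances linearly in thermal time from 0
  (emergence) through 1 (anthesis, after ``tsum1``) to 2 (maturity, after
  ``tsum2``).
* **Assimilation** — instantaneous canopy gross CO₂ uptake is the
  three-point Gaussian integral over canopy depth of the saturating leaf
  light response ``AMAX·(1 − exp(−EFF·I/AMAX))`` under an exponential
  diffuse light profile, integrated over the diurnal course with a second
  three-point Gaussian weighted by solar elevation.
* **Respiration and growth** — Q10 maintenance respiration (capped at the
  day's gross assimilation) is subtracted; the remainder is partitioned to
  root, leaf, stem and storage organ by development-stage-indexed fractions
  and converted to structural dry matter with organ-specific efficiencies.
* **Leaf dynamics** — leaf area expands exponentially (thermal-time limited)
  while the canopy is young, source-limited via the specific leaf area
  afterwards; leaf cohorts senesce once their physiological age exceeds the
  life span, plus a self-shading mortality above a critical LAI.

Potential yield is the storage-organ dry weight at maturity.  A full carbon
ledger (gross assimilation, maintenance, conversion losses, senesced
biomass) is carried so every run can be audited for mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crop_params import SOWING_DATE, CropParameterSet, get_params
from .weather import extraterrestrial_radiation

__all__ = [
    "CropState",
    "SimulationResult",
    "phenology_step",
    "daily_gross_assimilation",
    "maintenance_respiration",
    "run_potential",
    "simulate_station_years",
]

# three-point Gaussian abscissae/weights on (0, 1)
_XG = np.array([0.1127016653792583, 0.5, 0.8872983346207417])
_WG = np.array([0.2777777777777777, 0.4444444444444444, 0.2777777777777777])

_CO2_TO_CH2O = 30.0 / 44.0
_SEASON_END = (10, 31)  # simulations stop on 31 October if maturity not reached


@dataclass
class _LeafCohort:
    weight: float       # living leaf dry weight, kg/ha
    sla: float          # leaf area per weight at formation, ha/kg
    age: float = 0.0    # physiological age, days at 35 °C equivalent


@dataclass
class CropState:
    """Mutable crop state, advanced one day at a time."""

    emerged: bool = False
    mature: bool = False
    dvs: float = 0.0
    cum_em: float = 0.0   # thermal time sowing→emergence, °C·day
    cum1: float = 0.0     # thermal time emergence→anthesis
    cum2: float = 0.0     # thermal time anthesis→maturity
    lai: float = 0.0
    wrt: float = 0.0      # root dry weight, kg/ha
    wlv: float = 0.0      # living leaf dry weight
    wst: float = 0.0      # stem dry weight
    wso: float = 0.0      # storage-organ dry weight
    cohorts: list[_LeafCohort] = field(default_factory=list)
    # carbon ledger, kg CH2O/ha resp. kg DM/ha
    gross_total: float = 0.0
    maint_total: float = 0.0
    conversion_loss_total: float = 0.0
    senesced_total: float = 0.0
    initial_dw: float = 0.0

    def live_weight(self) -> float:
        return self.wrt + self.wlv + self.wst + self.wso

    def carbon_closure_error(self) -> float:
        """Relative mass-balance closure error of the run so far.

        Gross assimilate minus maintenance, conversion losses and senesced
        biomass must equal the net live-weight increment.
        """
        supplied = self.gross_total - self.maint_total - self.conversion_loss_total
        gained = (self.live_weight() - self.initial_dw) + self.senesced_total
        scale = max(self.gross_total, 1.0)
        return abs(supplied - gained) / scale


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one station-year potential-production run."""

    variety: str
    sowing_date: pd.Timestamp
    emergence_date: pd.Timestamp | None
    anthesis_date: pd.Timestamp | None
    maturity_date: pd.Timestamp | None
    termination_reason: str  # "maturity" or "season_end"
    potential_yield: float   # storage-organ dry weight, kg/ha
    growing_duration: int | None  # emergence → maturity, days
    total_biomass: float
    max_lai: float
    carbon_closure_error: float
    trajectory: pd.DataFrame | None = None


def phenology_step(state: CropState, tave: float, params: CropParameterSet) -> None:
    """Advance thermal-time phenology by one day (in place).

    The day's effective temperature ``max(Tave, 0)`` accrues wholly to the
    current phase; a phase transition fires on the first day its cumulative
    sum reaches the phase TSUM.
    """
    if state.mature:
        return
    teff = max(tave, 0.0)
    if not state.emerged:
        state.cum_em += teff
        if state.cum_em >= params.tsum_em:
            state.emerged = True
        return
    if state.dvs < 1.0:
        state.cum1 += teff
        state.dvs = min(state.cum1 / params.tsum1, 1.0)
    else:
        state.cum2 += teff
        state.dvs = 1.0 + min(state.cum2 / params.tsum2, 1.0)
        if state.cum2 >= params.tsum2:
            state.mature = True


_SCV = 0.2  # leaf scattering coefficient for visible light


def _instant_canopy_assimilation(
    par_dir: float,
    par_dif: float,
    sinb: float,
    lai: float,
    amax: float,
    params: CropParameterSet,
) -> float:
    """Instantaneous canopy gross assimilation, kg CO2/ha/h.

    Sunlit/shaded-leaf formulation: diffuse PAR and the diffuse component of
    scattered direct beam follow exponential extinction profiles; sunlit
    leaves additionally intercept the unscattered beam at an intensity set
    by solar elevation.  A three-point Gaussian integrates the saturating
    leaf light response ``AMAX·(1 − exp(−EFF·I/AMAX))`` over relative
    canopy depth.  ``par_dir``/``par_dif`` are instantaneous fluxes in
    J/m²/s; ``sinb`` is the sine of solar elevation.
    """
    if lai <= 0.0 or amax <= 0.0 or sinb <= 0.0 or (par_dir + par_dif) <= 0.0:
        return 0.0
    sqv = np.sqrt(1.0 - _SCV)
    refh = (1.0 - sqv) / (1.0 + sqv)            # canopy reflection, diffuse
    refs = refh * 2.0 / (1.0 + 1.6 * sinb)      # canopy reflection, direct
    kdif = params.kdif
    kdirbl = (0.5 / sinb) * kdif / (0.8 * sqv)  # black-leaf direct extinction
    kdirt = kdirbl * sqv                        # total direct extinction

    laic = _XG * lai
    # absorbed flux per unit leaf area: diffuse, total direct, unscattered direct
    visdf = (1.0 - refh) * par_dif * kdif * np.exp(-kdif * laic)
    vist = (1.0 - refs) * par_dir * kdirt * np.exp(-kdirt * laic)
    visd = (1.0 - _SCV) * par_dir * kdirbl * np.exp(-kdirbl * laic)
    visshd = visdf + vist - visd                # shaded leaves
    fgrsh = amax * (1.0 - np.exp(-params.eff * np.maximum(visshd, 0.0) / amax))
    # sunlit leaves: average over leaf angles of beam interception
    vispp = (1.0 - _SCV) * par_dir / sinb
    if vispp <= 1e-12:
        fgrsun = fgrsh
    else:
        fgrsun = amax * (
            1.0
            - (amax - fgrsh)
            * (1.0 - np.exp(-params.eff * vispp / amax))
            / (params.eff * vispp)
        )
    fslla = np.exp(-kdirbl * laic)              # sunlit leaf-area fraction
    fgl = fslla * fgrsun + (1.0 - fslla) * fgrsh
    return float(lai * np.dot(_WG, fgl))


def _diffuse_fraction(atmtr: float, sinb: float) -> float:
    """Diffuse fraction of incoming PAR from atmospheric transmission."""
    if atmtr <= 0.22:
        frdif = 1.0
    elif atmtr <= 0.35:
        frdif = 1.0 - 6.4 * (atmtr - 0.22) ** 2
    else:
        frdif = 1.47 - 1.66 * atmtr
    return max(frdif, 0.15 + 0.85 * (1.0 - np.exp(-0.1 / max(sinb, 1e-6))))


def daily_gross_assimilation(
    ra: float,
    daylength: float,
    lai: float,
    params: CropParameterSet,
    daytime_temp: float | None = None,
    dvs: float = 0.0,
    lat_doy: tuple[float, int] | None = None,
) -> float:
    """Daily canopy gross assimilation, kg CH₂O/ha/day.

    ``ra`` is daily global radiation in kJ/m²/day; half of it is taken as
    photosynthetically active.  The diurnal course of the instantaneous PAR
    flux follows solar elevation ``sinβ(1 + 0.4 sinβ)``; a three-point
    Gaussian over the daylight period integrates the canopy rate.  When
    ``lat_doy`` (latitude, day-of-year) is given the solar geometry uses it;
    otherwise a symmetric sine approximation based on daylength alone is
    used.

    The optional ``daytime_temp`` (°C) scales AMAX through the leaf
    temperature response.
    """
    if lai <= 0.0 or ra <= 0.0 or daylength <= 0.0:
        return 0.0
    amax = (
        params.amax if daytime_temp is None
        else params.amax_at(daytime_temp, dvs)
    )
    if amax <= 0.0:
        return 0.0

    par_day = 0.5 * ra * 1e3  # J/m²/day of PAR

    if lat_doy is not None:
        lat, doy = lat_doy
        delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
        sinld = np.sin(np.radians(lat)) * np.sin(delta)
        cosld = np.cos(np.radians(lat)) * np.cos(delta)
    else:
        # symmetric geometry reproducing the given daylength
        cos_half = np.cos(np.pi * daylength / 24.0)
        sinld = -cos_half / (1.0 + cos_half) if cos_half > -0.999 else 1.0
        cosld = 1.0 / (1.0 + cos_half) if cos_half > -0.999 else 0.0

    hours = 12.0 + 0.5 * daylength * (2.0 * _XG - 1.0)
    sinb = np.maximum(0.0, sinld + cosld * np.cos(2.0 * np.pi * (hours + 12.0) / 24.0))
    # integral of sinb(1+0.4 sinb) over the day, seconds
    aux = np.clip(sinld / cosld, -1.0, 1.0) if cosld > 0 else 1.0
    dsinbe = 3600.0 * (
        daylength * (sinld + 0.4 * (sinld**2 + 0.5 * cosld**2))
        + 12.0 * cosld * (2.0 + 3.0 * 0.4 * sinld) * np.sqrt(max(0.0, 1.0 - aux**2)) / np.pi
    )
    if dsinbe <= 0.0:
        return 0.0
    flux = par_day * sinb * (1.0 + 0.4 * sinb) / dsinbe  # J/m²/s at each Gauss hour
    # solar constant scaled to the day (visible half), for the transmission
    doy_eff = lat_doy[1] if lat_doy is not None else 172
    sc_vis = 0.5 * 1370.0 * (1.0 + 0.033 * np.cos(2.0 * np.pi * doy_eff / 365.0))
    rates = []
    for f, sb in zip(flux, sinb):
        if sb <= 0.0 or f <= 0.0:
            rates.append(0.0)
            continue
        atmtr = f / (sc_vis * sb)
        frdif = _diffuse_fraction(atmtr, sb)
        rates.append(
            _instant_canopy_assimilation(f * (1.0 - frdif), f * frdif, sb, lai, amax, params)
        )
    fgros_co2 = daylength * float(np.dot(_WG, rates))  # kg CO2/ha/day
    return fgros_co2 * _CO2_TO_CH2O


def maintenance_respiration(state: CropState, tave: float, params: CropParameterSet) -> float:
    """Daily maintenance respiration demand, kg CH₂O/ha/day (uncapped)."""
    base = (
        params.rml * state.wlv
        + params.rms * state.wst
        + params.rmo * state.wso
        + params.rmr * state.wrt
    )
    return base * params.q10 ** ((tave - params.tref) / 10.0)


def _partition_and_grow(state: CropState, asrc: float, params: CropParameterSet) -> float:
    """Distribute net assimilate over organs; returns the leaf DM increment."""
    fr = params.root_fraction(state.dvs)
    fl, fs, fo = params.shoot_fractions(state.dvs)
    shoot = asrc * (1.0 - fr)
    d_rt = asrc * fr * params.cvr
    d_lv = shoot * fl * params.cvl
    d_st = shoot * fs * params.cvs
    d_so = shoot * fo * params.cvo
    state.wrt += d_rt
    state.wst += d_st
    state.wso += d_so
    state.wlv += d_lv
    state.conversion_loss_total += asrc - (d_rt + d_lv + d_st + d_so)
    return d_lv


def _leaf_dynamics(state: CropState, d_lv: float, tave: float, params: CropParameterSet) -> None:
    """Age, kill and grow leaf cohorts; refresh LAI (in place)."""
    # physiological ageing: SPAN is the life span at 35 °C, ageing scales
    # linearly with temperature above the 0 °C base
    fysage = max(0.0, tave / 35.0)
    for c in state.cohorts:
        c.age += fysage
    died = 0.0
    survivors = []
    for c in state.cohorts:
        if c.age >= params.span:
            died += c.weight
        else:
            survivors.append(c)
    # self-shading mortality above the critical LAI: a relative death rate,
    # applied proportionally across cohorts so the response stays smooth
    lai_now = sum(c.weight * c.sla for c in survivors)
    if lai_now > params.laicr:
        rate = min(0.03, 0.03 * (lai_now - params.laicr) / params.laicr)
        for c in survivors:
            loss = c.weight * rate
            c.weight -= loss
            died += loss
        survivors = [c for c in survivors if c.weight > 0.0]
    state.cohorts = survivors
    state.senesced_total += died
    state.wlv -= died

    # new growth: exponential (thermal-time-limited) while the canopy is
    # juvenile, otherwise source-limited through SLA
    if d_lv > 0.0:
        lai_now = sum(c.weight * c.sla for c in state.cohorts)
        if state.dvs < 0.3 and lai_now < 0.75:
            teff = min(max(tave, 0.0), 30.0)
            glaiex = lai_now * (np.exp(params.rgrlai * teff) - 1.0)
            d_lai = min(glaiex, d_lv * params.sla) if lai_now > 0 else d_lv * params.sla
            sla_eff = d_lai / d_lv
        else:
            sla_eff = params.sla
        state.cohorts.append(_LeafCohort(weight=d_lv, sla=sla_eff))
    state.lai = sum(c.weight * c.sla for c in state.cohorts)


def _initialize_emerged(state: CropState, params: CropParameterSet) -> None:
    fr = params.root_fraction(0.0)
    fl, fs, _fo = params.shoot_fractions(0.0)
    state.wrt = params.tdwi * fr
    state.wlv = params.tdwi * (1.0 - fr) * fl
    state.wst = params.tdwi * (1.0 - fr) * fs
    state.cohorts = [_LeafCohort(weight=state.wlv, sla=params.sla)]
    state.lai = state.wlv * params.sla
    state.initial_dw = state.live_weight()


def run_potential(
    weather: pd.DataFrame,
    params: CropParameterSet,
    sowing_date,
    latitude: float | None = None,
    keep_trajectory: bool = False,
) -> SimulationResult:
    """Run one potential-production season.

    ``weather`` must carry one row per calendar day with columns ``date``,
    ``tave``, ``tmax``, ``ra`` (kJ/m²/day) and either ``daylength`` (h) or a
    ``latitude`` argument to compute it.  The run starts on ``sowing_date``
    and ends at maturity or on 31 October, whichever comes first.
    """
    sowing = pd.Timestamp(sowing_date)
    end = pd.Timestamp(year=sowing.year, month=_SEASON_END[0], day=_SEASON_END[1])
    w = weather[(weather["date"] >= sowing) & (weather["date"] <= end)].sort_values("date")
    if w.empty:
        raise ValueError(f"no weather rows covering {sowing.date()}")
    dates = w["date"].to_numpy()
    deltas = np.diff(dates).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        gap_at = pd.Timestamp(dates[int(np.argmax(deltas != 1))]) + pd.Timedelta(days=1)
        raise ValueError(f"weather gap inside the run, first missing day {gap_at.date()}")

    if "daylength" in w.columns:
        daylengths = w["daylength"].to_numpy(float)
    elif latitude is not None:
        _, daylengths = extraterrestrial_radiation(latitude, w["date"].dt.dayofyear.to_numpy())
    else:
        raise ValueError("weather lacks a daylength column and no latitude given")

    tave = w["tave"].to_numpy(float)
    tmax = w["tmax"].to_numpy(float)
    ra = w["ra"].to_numpy(float)
    doy = w["date"].dt.dayofyear.to_numpy()
    if "tmin" in w.columns:
        tmin = w["tmin"].to_numpy(float)
    else:
        tmin = 2.0 * tave - tmax
    # 7-day running mean of Tmin (shorter window at the season start)
    csum = np.concatenate([[0.0], np.cumsum(tmin)])
    idx = np.arange(len(tmin))
    lo = np.maximum(idx - 6, 0)
    tmin_week = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)

    state = CropState()
    emergence_date = anthesis_date = maturity_date = None
    traj = [] if keep_trajectory else None
    max_lai = 0.0

    for i in range(len(w)):
        if state.emerged and not state.mature:
            daytime_temp = 0.5 * (tmax[i] + tave[i])
            gross = daily_gross_assimilation(
                ra[i], daylengths[i], state.lai, params,
                daytime_temp=daytime_temp, dvs=state.dvs,
                lat_doy=(latitude, int(doy[i])) if latitude is not None else None,
            )
            gross *= params.cold_night_factor(tmin_week[i])
            maint = min(gross, maintenance_respiration(state, tave[i], params))
            asrc = gross - maint
            state.gross_total += gross
            state.maint_total += maint
            d_lv = _partition_and_grow(state, asrc, params)
            _leaf_dynamics(state, d_lv, tave[i], params)
            max_lai = max(max_lai, state.lai)

        was_emerged, was_past_anthesis = state.emerged, state.dvs >= 1.0
        phenology_step(state, tave[i], params)
        date_i = pd.Timestamp(dates[i])
        if state.emerged and not was_emerged:
            emergence_date = date_i
            _initialize_emerged(state, params)
        if state.dvs >= 1.0 and not was_past_anthesis:
            anthesis_date = date_i
        if state.mature:
            maturity_date = date_i

        if traj is not None:
            traj.append({
                "date": date_i, "dvs": state.dvs, "lai": state.lai,
                "wrt": state.wrt, "wlv": state.wlv, "wst": state.wst, "wso": state.wso,
            })
        if state.mature:
            break

    reason = "maturity" if state.mature else "season_end"
    duration = (
        int((maturity_date - emergence_date).days)
        if maturity_date is not None and emergence_date is not None
        else None
    )
    return SimulationResult(
        variety=params.variety,
        sowing_date=sowing,
        emergence_date=emergence_date,
        anthesis_date=anthesis_date,
        maturity_date=maturity_date,
        termination_reason=reason,
        potential_yield=state.wso,
        growing_duration=duration,
        total_biomass=state.live_weight() + state.senesced_total,
        max_lai=max_lai,
        carbon_closure_error=state.carbon_closure_error(),
        trajectory=pd.DataFrame(traj) if traj is not None else None,
    )


def simulate_station_years(
    daily: pd.DataFrame,
    variety: str,
    station_id: str,
    latitude: float | None = None,
    params: CropParameterSet | None = None,
) -> pd.DataFrame:
    """Run every complete year of a derived daily series for one station.

    Returns the tidy station-year table (station_id, year, variety, sowing,
    emergence, anthesis, maturity, duration, yield_kg_ha, termination_reason).
    """
    p = params or get_params(variety)
    month, day = SOWING_DATE[variety]
    rows = []
    for year, grp in daily.groupby(daily["date"].dt.year):
        sowing = pd.Timestamp(year=int(year), month=month, day=day)
        end = pd.Timestamp(year=int(year), month=_SEASON_END[0], day=_SEASON_END[1])
        have = grp[(grp["date"] >= sowing) & (grp["date"] <= end)]
        if len(have) < (end - sowing).days + 1:
            continue  # incomplete season
        res = run_potential(grp, p, sowing, latitude=latitude)
        rows.append({
            "station_id": station_id,
            "year": int(year),
            "variety": variety,
            "sowing": res.sowing_date.date().isoformat(),
            "emergence": res.emergence_date.date().isoformat() if res.emergence_date else "",
            "anthesis": res.anthesis_date.date().isoformat() if res.anthesis_date else "",
            "maturity": res.maturity_date.date().isoformat() if res.maturity_date else "",
            "duration": res.growing_duration if res.growing_duration is not None else np.nan,
            "yield_kg_ha": res.potential_yield,
            "termination_reason": res.termination_reason,
        })
    return pd.DataFrame(rows)
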