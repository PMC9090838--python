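"""Potential-production simulator: phenology, assimilation, mass balance."""

import numpy as np
import pandas as pd
import pytest

import chingke as ck
from chingke.crop import (
    CropState,
    _diffuse_fraction,
    _instant_canopy_assimilation,
    daily_gross_assimilation,
    maintenance_respiration,
    phenology_step,
    run_potential,
)
from chingke.crop_params import get_params


def phenology_oracle(tave_series, tsums):
    """First day index each phase-wise cumulative sum reaches its threshold.

    Phases accumulate disjointly: the transition day's temperature counts
    toward the phase it completes, and the next phase starts the following
    day (half-open phase intervals).
    """
    days = []
    phase, acc = 0, 0.0
    for i, t in enumerate(tave_series):
        acc += max(t, 0.0)
        if acc >= tsums[phase]:
            days.append(i)
            phase += 1
            acc = 0.0
            if phase == len(tsums):
                break
    return days


class TestPhenology:
    def test_constant_temperature_emergence_day(self):
        p = get_params("Chaiqing-1")
        st = CropState()
        days = 0
        while not st.emerged:
            phenology_step(st, 10.0, p)
            days += 1
        assert days == 10  # 100 °C·day at 10 °C/day

    def test_no_development_below_base(self):
        p = get_params("Chaiqing-1")
        st = CropState()
        for _ in range(50):
            phenology_step(st, -2.0, p)
        assert not st.emerged and st.dvs == 0.0

    def test_variety_thermal_requirements(self):
        # full-cycle requirements per variety: 100+650+850, 100+700+950, 100+800+1050
        totals = {"Chaiqing-1": 1600.0, "Zangqing-2000": 1750.0, "Diqing-1": 1950.0}
        for variety, total in totals.items():
            p = get_params(variety)
            assert p.tsum_em == 100.0
            assert p.tsum_em + p.tsum1 + p.tsum2 == total

    def test_run_dates_match_cumulative_threshold_oracle(self, constant_weather):
        p = get_params("Chaiqing-1")
        rng = np.random.default_rng(11)
        w = constant_weather()
        w["tave"] = rng.uniform(2.0, 18.0, len(w))
        sowing = pd.Timestamp("2001-04-10")
        res = run_potential(w, p, sowing)
        tser = w[w["date"] >= sowing]["tave"].to_numpy()
        d_em, d_an, d_mat = phenology_oracle(tser, [p.tsum_em, p.tsum1, p.tsum2])
        assert (res.emergence_date - sowing).days == d_em
        assert (res.anthesis_date - sowing).days == d_an
        assert (res.maturity_date - sowing).days == d_mat


class TestAssimilation:
    def test_zero_without_canopy_or_light(self):
        p = get_params("Chaiqing-1")
        assert daily_gross_assimilation(20000.0, 13.0, 0.0, p) == 0.0
        assert daily_gross_assimilation(0.0, 13.0, 3.0, p) == 0.0

    def test_monotone_in_radiation_and_lai(self):
        p = get_params("Chaiqing-1")
        gs = [daily_gross_assimilation(ra, 13.0, 3.0, p, lat_doy=(30.0, 180))
              for ra in np.linspace(1000, 30000, 20)]
        assert np.all(np.diff(gs) > 0)
        gl = [daily_gross_assimilation(20000.0, 13.0, lai, p, lat_doy=(30.0, 180))
              for lai in np.linspace(0.1, 8, 20)]
        assert np.all(np.diff(gl) > 0)

    def test_bounded_by_saturated_canopy(self):
        p = get_params("Chaiqing-1")
        lai, n = 4.0, 13.0
        g = daily_gross_assimilation(30000.0, n, lai, p, lat_doy=(30.0, 172))
        assert g < p.amax * lai * n * 30.0 / 44.0

    def test_gaussian_integration_matches_fine_grid_oracle(self):
        """3x3 Gaussian day/canopy quadrature vs dense trapezoid integration
        of the identical leaf-level light response."""
        p = get_params("Chaiqing-1")
        lat, doy, ra, lai = 30.0, 180, 22000.0, 3.5
        _, daylength = ck.extraterrestrial_radiation(lat, doy)
        got = daily_gross_assimilation(ra, daylength, lai, p, lat_doy=(lat, doy))

        # --- dense oracle, explicit loops -----------------------------------
        delta = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
        sinld = np.sin(np.radians(lat)) * np.sin(delta)
        cosld = np.cos(np.radians(lat)) * np.cos(delta)
        aux = sinld / cosld
        dsinbe = 3600.0 * (
            daylength * (sinld + 0.4 * (sinld**2 + 0.5 * cosld**2))
            + 12.0 * cosld * (2.0 + 1.2 * sinld) * np.sqrt(1 - aux**2) / np.pi
        )
        par_day = 0.5 * ra * 1e3
        sc_vis = 0.5 * 1370.0 * (1 + 0.033 * np.cos(2 * np.pi * doy / 365.0))
        hours = np.linspace(12 - daylength / 2, 12 + daylength / 2, 101)
        canopy = np.linspace(0.0, 1.0, 101)
        rates = []
        for h in hours:
            sinb = max(0.0, sinld + cosld * np.cos(2 * np.pi * (h + 12) / 24))
            if sinb <= 0:
                rates.append(0.0)
                continue
            flux = par_day * sinb * (1 + 0.4 * sinb) / dsinbe
            frdif = _diffuse_fraction(flux / (sc_vis * sinb), sinb)
            pdir, pdif = flux * (1 - frdif), flux * frdif
            sqv = np.sqrt(0.8)
            refh = (1 - sqv) / (1 + sqv)
            refs = refh * 2 / (1 + 1.6 * sinb)
            kdirbl = (0.5 / sinb) * p.kdif / (0.8 * sqv)
            kdirt = kdirbl * sqv
            prof = []
            for x in canopy:
                laic = x * lai
                visshd = (
                    (1 - refh) * pdif * p.kdif * np.exp(-p.kdif * laic)
                    + (1 - refs) * pdir * kdirt * np.exp(-kdirt * laic)
                    - 0.8 * pdir * kdirbl * np.exp(-kdirbl * laic)
                )
                fgrsh = p.amax * (1 - np.exp(-p.eff * max(visshd, 0.0) / p.amax))
                vispp = 0.8 * pdir / sinb
                if vispp <= 1e-12:
                    fgrsun = fgrsh
                else:
                    fgrsun = p.amax * (
                        1 - (p.amax - fgrsh) * (1 - np.exp(-p.eff * vispp / p.amax))
                        / (p.eff * vispp)
                    )
                fslla = np.exp(-kdirbl * laic)
                prof.append(fslla * fgrsun + (1 - fslla) * fgrsh)
            rates.append(lai * np.trapezoid(prof, canopy))
        oracle = np.trapezoid(rates, hours) * 30.0 / 44.0
        assert got == pytest.approx(oracle, rel=0.02)


class TestRespiration:
    def test_zero_weights_zero_respiration(self):
        p = get_params("Chaiqing-1")
        assert maintenance_respiration(CropState(), 20.0, p) == 0.0

    def test_reference_temperature_weighted_sum(self):
        p = get_params("Chaiqing-1")
        st = CropState(wlv=100.0, wst=200.0, wso=50.0, wrt=80.0)
        expected = 0.03 * 100 + 0.015 * 200 + 0.01 * 50 + 0.01 * 80
        assert maintenance_respiration(st, p.tref, p) == pytest.approx(expected)

    def test_q10_doubling_ten_degrees_above_reference(self):
        p = get_params("Chaiqing-1")
        st = CropState(wlv=1000.0)
        assert maintenance_respiration(st, p.tref + 10.0, p) == pytest.approx(60.0)


class TestPartitioning:
    def test_fractions_sum_to_one_over_development(self):
        p = get_params("Chaiqing-1")
        for dvs in np.linspace(0, 2, 101):
            fl, fs, fo = p.shoot_fractions(float(dvs))
            assert fl + fs + fo == pytest.approx(1.0, abs=1e-9)
            assert min(fl, fs, fo) >= -1e-12

    def test_hand_stepped_increments_with_fixed_fractions(self):
        from chingke.crop import _partition_and_grow

        p = get_params(
            "Chaiqing-1",
            frtb=((0.0, 0.2), (2.0, 0.2)),
            fltb=((0.0, 0.625), (2.0, 0.625)),  # shoot: 0.5 leaf / 0.3 stem / 0.2 organ
            fotb=((0.0, 0.0), (2.0, 0.0)),
            cvl=0.7, cvs=0.7, cvo=0.7, cvr=0.7,
        )
        # with root fraction 0.2, shoot split 0.625/0.375 of the remaining 0.8
        st = CropState(dvs=0.5)
        a = 100.0
        _partition_and_grow(st, a, p)
        assert st.wrt == pytest.approx(0.7 * 0.2 * a)
        assert st.wlv == pytest.approx(0.7 * 0.5 * a)
        assert st.wst == pytest.approx(0.7 * 0.3 * a)

    def test_storage_organ_dominates_late(self):
        p = get_params("Chaiqing-1")
        fl, fs, fo = p.shoot_fractions(1.8)
        assert fo > 0.9 and fo > fl and fo > fs


class TestLeafDynamics:
    def test_cohort_fully_senesced_after_span_days_at_35(self, constant_weather):
        p = get_params("Chaiqing-1")
        w = constant_weather(tave=35.0, tdr=0.0)
        res = run_potential(w, p, pd.Timestamp("2001-04-05"), keep_trajectory=True)
        tr = res.trajectory
        # at 35 °C ageing runs at 1 day/day: any leaf area present on day d
        # is gone by day d + SPAN unless replaced; after anthesis leaf growth
        # stops, so LAI must vanish within SPAN days of the last leaf growth
        last_growth = tr[tr["wlv"].diff() > 0].index.max()
        after = tr.loc[last_growth + int(p.span) + 1:]
        if len(after):
            assert after["lai"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_lai_trajectory_unimodal_on_standard_season(self, derived_station):
        m, d = derived_station
        p = get_params(m.variety)
        res = run_potential(d, p, pd.Timestamp("2002-04-10"), latitude=m.latitude,
                            keep_trajectory=True)
        lai = res.trajectory["lai"].to_numpy()
        peak = int(np.argmax(lai))
        rising, falling = lai[: peak + 1], lai[peak:]
        assert np.all(np.diff(rising) >= -1e-9)
        # allow small wiggles from cohort growth while mostly declining
        assert falling[-1] < 0.05 * lai[peak]


class TestRunPotential:
    def test_dark_season_produces_no_yield(self, constant_weather):
        p = get_params("Chaiqing-1")
        w = constant_weather(ra=0.0)
        res = run_potential(w, p, pd.Timestamp("2001-04-10"))
        assert res.potential_yield == pytest.approx(0.0, abs=1e-9)

    def test_zero_amax_gives_no_yield(self, derived_station):
        m, d = derived_station
        p = get_params(m.variety, amax=0.0)
        res = run_potential(d, p, pd.Timestamp("2002-04-10"), latitude=m.latitude)
        assert res.potential_yield == pytest.approx(0.0, abs=1e-6)

    def test_radiation_scaling_never_decreases_yield(self, derived_station):
        m, d = derived_station
        p = get_params(m.variety)
        base = run_potential(d, p, pd.Timestamp("2002-04-10"), latitude=m.latitude)
        boosted = d.copy()
        boosted["ra"] = boosted["ra"] * 1.2
        up = run_potential(boosted, p, pd.Timestamp("2002-04-10"), latitude=m.latitude)
        assert up.potential_yield >= base.potential_yield

    def test_carbon_balance_closure(self, derived_station):
        m, d = derived_station
        p = get_params(m.variety)
        for year in (2001, 2002, 2003):
            res = run_potential(d, p, pd.Timestamp(f"{year}-04-10"), latitude=m.latitude)
            assert res.carbon_closure_error < 1e-6

    def test_deterministic_reruns_bit_identical(self, derived_station):
        m, d = derived_station
        p = get_params(m.variety)
        a = run_potential(d, p, pd.Timestamp("2002-04-10"), latitude=m.latitude)
        b = run_potential(d, p, pd.Timestamp("2002-04-10"), latitude=m.latitude)
        assert a.potential_yield == b.potential_yield
        assert a.maturity_date == b.maturity_date
        assert a.total_biomass == b.total_biomass

    def test_weather_gap_raises_with_missing_date(self, constant_weather):
        p = get_params("Chaiqing-1")
        w = constant_weather()
        w = w[w["date"] != pd.Timestamp("2001-06-15")]
        with pytest.raises(ValueError, match="gap"):
            run_potential(w, p, pd.Timestamp("2001-04-10"))

    def test_cold_season_terminates_at_season_end(self, constant_weather):
        p = get_params("Chaiqing-1")
        w = constant_weather(tave=3.0)
        res = run_potential(w, p, pd.Timestamp("2001-04-10"))
        assert res.termination_reason == "season_end"
        assert res.maturity_date is None
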