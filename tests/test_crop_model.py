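"""Crop-model physics: Beer's law, Farquhar kinetics, the soil bucket,
stress multipliers, and the daily growth loop (scalar and jitted paths)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soyco2 import solar
from soyco2.crop_model import (
    CalibParams,
    CellForcing,
    PhysioConstants,
    WeatherDaily,
    absorbed_par_fraction,
    arrhenius,
    biomass_to_yield,
    cold_stress,
    drought_stress,
    farquhar_gross_assimilation,
    grow_day,
    initial_state,
    simulate_season,
    simulate_years,
    soil_fluxes,
    soil_water_step,
    weather_from_frame,
    EA_VCMAX,
    EA_JMAX,
    EA_KC,
    EA_KO,
    EA_GAMMA_STAR,
    G_CH2O_PER_UMOL_CO2,
    PAR_FRACTION,
    UMOL_PER_J,
)


def day(doy=180, tmean=22.0, tmin=16.0, tmax=28.0, precip=0.0, srad=22.0):
    return WeatherDaily(doy, tmean, tmin, tmax, precip, srad)


class TestAbsorbedPar:
    def test_no_canopy_absorbs_nothing(self):
        assert absorbed_par_fraction(0.0, 0.5) == 0.0

    def test_printed_relative_gains(self):
        # Canopy closure: going from LAI 6 to 7 gains far less absorbed PAR
        # than the same 17% LAI increase applied to an open canopy at LAI 4.
        gain_dense = 100 * (absorbed_par_fraction(7.0, 0.5)
                            / absorbed_par_fraction(6.0, 0.5) - 1)
        gain_open = 100 * (absorbed_par_fraction(4.0 * 7 / 6, 0.5)
                           / absorbed_par_fraction(4.0, 0.5) - 1)
        assert round(gain_dense, 1) == 2.1
        assert round(gain_open, 1) == 4.4

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            absorbed_par_fraction(-0.1, 0.5)
        with pytest.raises(ValueError):
            absorbed_par_fraction(1.0, 0.0)

    @given(st.floats(0.0, 15.0), st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing(self, lai, k):
        f = absorbed_par_fraction(lai, k)
        assert 0.0 <= f < 1.0
        assert absorbed_par_fraction(lai + 0.1, k) > f


class TestFarquhar:
    def test_dark_rate_clips_to_zero(self, pc):
        assert farquhar_gross_assimilation(380.0, 25.0, 0.0, pc) == 0.0

    def test_monotone_saturating_in_co2(self, pc):
        a = [farquhar_gross_assimilation(ca, 25.0, 1500.0, pc)
             for ca in (339.0, 377.0, 677.0)]
        assert a[0] < a[1] < a[2]
        # concave: the marginal ppm gain shrinks at high CO2
        lo = (farquhar_gross_assimilation(360.0, 25.0, 1500.0, pc) - a[0]) / 21.0
        hi = (farquhar_gross_assimilation(700.0, 25.0, 1500.0, pc) - a[2]) / 23.0
        assert hi < lo

    def test_matches_independent_evaluation(self, pc):
        """Close-form re-evaluation of the kinetics at one operating point."""
        ca, tleaf, par = 380.0, 25.0, 1000.0
        tk = tleaf + 273.15
        arr = lambda ea: math.exp(ea * (tk - 298.15) / (8.314 * 298.15 * tk))
        ci = pc.ci_ratio * ca
        vc = pc.vcmax25 * arr(EA_VCMAX)
        kc = pc.kc25 * arr(EA_KC)
        ko = pc.ko25 * arr(EA_KO)
        gs = pc.gamma_star25 * arr(EA_GAMMA_STAR)
        ac = vc * (ci - gs) / (ci + kc * (1 + pc.o2 / ko))
        jm = pc.jmax25 * arr(EA_JMAX)
        b = pc.phi_q * par + jm
        j = (b - math.sqrt(b * b - 4 * pc.theta_light * pc.phi_q * par * jm)) / (
            2 * pc.theta_light
        )
        aj = j * (ci - gs) / (4 * ci + 8 * gs)
        expected = max(min(ac, aj) - pc.rd_frac * vc, 0.0)
        got = farquhar_gross_assimilation(ca, tleaf, par, pc)
        assert got == pytest.approx(expected, abs=1e-12)
        # at 25 degC all Arrhenius factors are exactly 1
        assert float(arrhenius(25.0, EA_VCMAX)) == pytest.approx(1.0)

    def test_co2_sens_scales_capacity(self, pc):
        low = farquhar_gross_assimilation(380.0, 25.0, 1500.0, pc, co2_sens=0.8)
        high = farquhar_gross_assimilation(380.0, 25.0, 1500.0, pc, co2_sens=1.2)
        assert high > low


class TestSoilBucket:
    def test_no_rain_no_demand_is_steady(self, pc):
        # tmax == tmin makes the Hargreaves demand vanish
        w = WeatherDaily(180, 20.0, 20.0, 20.0, 0.0, 20.0)
        state = initial_state(pc)
        assert soil_water_step(state, w, pc, lat=40.0) == state.soil_water

    def test_capacity_is_never_exceeded(self, pc):
        state = initial_state(pc)
        state.soil_water = pc.awc
        fx = soil_fluxes(pc.awc, day(precip=120.0), pc, lat=40.0)
        assert fx.soil_water <= pc.awc
        assert fx.runoff > 0 and fx.drainage > 0
        # balance: storage change equals the sum of fluxes
        assert fx.soil_water - pc.awc == pytest.approx(
            120.0 - fx.runoff - fx.et_actual - fx.drainage, abs=1e-12
        )

    def test_thirty_day_conservation(self, pc, rng):
        """Cumulative flux bookkeeping closes the balance to 1e-9 mm."""
        s = 0.4 * pc.awc
        total_in, total_out = 0.0, 0.0
        s0 = s
        for i in range(30):
            precip = float(rng.gamma(0.7, 8.0)) if rng.random() < 0.4 else 0.0
            w = day(doy=150 + i, precip=precip)
            fx = soil_fluxes(s, w, pc, lat=40.0)
            total_in += precip
            total_out += fx.runoff + fx.et_actual + fx.drainage
            s = fx.soil_water
        assert s - s0 == pytest.approx(total_in - total_out, abs=1e-9)


class TestStressMultipliers:
    def test_full_storage_and_zero_sensitivity(self, pc):
        assert drought_stress(pc.awc, pc.awc, 1.7) == 1.0
        assert drought_stress(0.3 * pc.awc, pc.awc, 0.0) == 1.0

    def test_drought_monotone_in_storage(self, pc):
        grid = np.linspace(0.05, 1.0, 25) * pc.awc
        vals = [drought_stress(s, pc.awc, 1.2) for s in grid]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert drought_stress(0.2 * pc.awc, pc.awc, 1.2) <= drought_stress(
            0.8 * pc.awc, pc.awc, 1.2
        )

    def test_cold_threshold_behaviour(self):
        assert cold_stress(13.0, 8.0, 0.3) == 1.0  # 5 degC above threshold
        assert cold_stress(-20.0, 8.0, 0.0) == 1.0  # sensitivity off
        assert cold_stress(4.0, 8.0, 0.3) <= cold_stress(7.0, 8.0, 0.3)
        assert cold_stress(-100.0, 8.0, 0.5) == 0.0  # bounded at zero


class TestGrowDay:
    def test_dark_day_updates_soil_only(self, pc, cp):
        state = initial_state(pc)
        w = day(srad=0.0, precip=12.0)
        new = grow_day(state, w, 370.0, pc, cp, lat=40.0)
        assert new.biomass_above == state.biomass_above
        assert new.biomass_leaf == state.biomass_leaf
        assert new.soil_water > state.soil_water

    def test_biomass_never_declines(self, pc, cp, usa_weather):
        sub = usa_weather[(usa_weather.year == 1990)].reset_index(drop=True)
        weather = weather_from_frame(sub)[134:200]
        state = initial_state(pc)
        prev = state.biomass_above
        for w in weather:
            state = grow_day(state, w, 370.0, pc, cp, lat=40.5)
            assert state.biomass_above >= prev
            assert state.lai == pytest.approx(pc.sla * state.biomass_leaf)
            prev = state.biomass_above

    def test_three_day_hand_bookkeeping(self, pc, cp):
        """Step-by-step recomputation of three fixed days."""
        days = [
            day(doy=160, tmean=20.0, tmin=14.0, tmax=26.0, precip=0.0, srad=24.0),
            day(doy=161, tmean=15.0, tmin=10.0, tmax=20.0, precip=8.0, srad=12.0),
            day(doy=162, tmean=25.0, tmin=18.0, tmax=32.0, precip=0.0, srad=28.0),
        ]
        lat = 40.0
        state = initial_state(pc)
        b_above, b_leaf, s, gdd = (
            state.biomass_above,
            state.biomass_leaf,
            state.soil_water,
            0.0,
        )
        for w in days:
            daylen_s = float(solar.daylength_hours(lat, w.day_of_year)) * 3600.0
            par = w.srad * 1e6 * PAR_FRACTION * UMOL_PER_J / daylen_s
            a = farquhar_gross_assimilation(370.0, w.tmean, par, pc, cp.co2_sens)
            fabs = 1.0 - math.exp(-pc.k_ext * pc.sla * b_leaf)
            ds = (s / pc.awc) ** cp.drought_sens
            cs = max(1.0 - cp.cold_sens * max(cp.cold_threshold - w.tmean, 0.0), 0.0)
            gain = a * fabs * ds * cs * daylen_s * G_CH2O_PER_UMOL_CO2 * pc.growth_eff
            b_above += gain
            b_leaf += pc.leaf_partition * gain  # well before the leaf stage ends
            gdd += max(w.tmean - pc.gdd_base, 0.0)
            fx = soil_fluxes(s, w, pc, lat)
            s = fx.soil_water
            state = grow_day(state, w, 370.0, pc, cp, lat)
            assert state.biomass_above == pytest.approx(b_above, rel=1e-12)
            assert state.biomass_leaf == pytest.approx(b_leaf, rel=1e-12)
            assert state.soil_water == pytest.approx(s, rel=1e-12)
            assert state.gdd_accum == pytest.approx(gdd, rel=1e-12)


class TestSimulateSeason:
    def test_zero_yield_scale_and_trend(self, pc, usa_weather):
        cp0 = CalibParams(yield_scale=1e-12, tech_intercept=0.0, tech_slope=0.0)
        sub = weather_from_frame(
            usa_weather[usa_weather.year == 1995].reset_index(drop=True)
        )
        res = simulate_season(sub, 370.0, 1995, pc, cp0, "north", lat=40.5)
        assert res.yield_t_ha == pytest.approx(0.0, abs=1e-9)
        assert res.final_biomass > 0

    def test_co2_monotonicity_and_determinism(self, pc, cp, usa_weather):
        sub = weather_from_frame(
            usa_weather[usa_weather.year == 1995].reset_index(drop=True)
        )
        lo = simulate_season(sub, 339.0, 1995, pc, cp, "north", lat=40.5)
        hi = simulate_season(sub, 377.0, 1995, pc, cp, "north", lat=40.5)
        hi2 = simulate_season(sub, 377.0, 1995, pc, cp, "north", lat=40.5)
        assert hi.yield_t_ha >= lo.yield_t_ha
        assert hi == hi2  # bit-identical rerun

    def test_incomplete_window_is_an_error(self, pc, cp, usa_weather):
        sub = weather_from_frame(
            usa_weather[(usa_weather.year == 1995) & (usa_weather.doy <= 200)]
            .reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="too short"):
            simulate_season(sub, 370.0, 1995, pc, cp, "north", lat=40.5)
        with pytest.raises(ValueError, match="planting day"):
            simulate_season(sub[:100], 370.0, 1995, pc, cp, "north", lat=40.5)


class TestFastPathEquivalence:
    @pytest.mark.parametrize("which", ["north", "south"])
    def test_scalar_and_jitted_paths_agree(self, pc, cp, usa_weather,
                                           brazil_weather, cell_specs, which):
        spec = cell_specs[0] if which == "north" else cell_specs[1]
        weather = usa_weather if which == "north" else brazil_weather
        years = [1980, 1993, 2006]
        forcing = CellForcing.build(weather, spec.lat, which, years, pc)
        fast = simulate_years(forcing, 370.0, cp)
        for i, year in enumerate(years):
            plant_year = year if which == "north" else year - 1
            sub = weather[
                ((weather.year == plant_year) & (weather.doy >= 1))
                | (weather.year == plant_year + 1)
            ].reset_index(drop=True)
            res = simulate_season(
                weather_from_frame(sub), 370.0, year, pc, cp, which, spec.lat
            )
            assert res.yield_t_ha == pytest.approx(fast.yields[i], abs=1e-9)
            assert res.final_biomass == pytest.approx(fast.final_biomass[i], abs=1e-6)
            assert res.lai_max == pytest.approx(fast.lai_max[i], abs=1e-9)


class TestYieldResponseShape:
    def test_monotone_and_concave_in_co2(self, pc, cp, usa_weather, cell_specs):
        forcing = CellForcing.build(usa_weather, cell_specs[0].lat, "north",
                                    [2000], pc)
        grid = np.arange(300.0, 701.0, 50.0)
        yields = np.array(
            [simulate_years(forcing, ca, cp).yields[0] for ca in grid]
        )
        assert np.all(np.diff(yields) >= 0)
        gain_350 = (yields[2] - yields[0]) / 100.0  # per ppm around 350
        gain_600 = (yields[-1] - yields[-3]) / 100.0  # per ppm around 650
        assert gain_600 < gain_350

    def test_technology_trend_is_exactly_linear(self, pc, usa_weather, cell_specs):
        """With stresses off and one fixed season, yield is linear in year."""
        cp = CalibParams(drought_sens=0.0, cold_sens=0.0, tech_slope=0.025,
                         tech_intercept=0.3, yield_scale=0.35)
        forcing = CellForcing.build(usa_weather, cell_specs[0].lat, "north",
                                    [1999], pc)
        biomass = simulate_years(forcing, 370.0, cp).final_biomass[0]
        yields = [
            biomass_to_yield(biomass, year, cp) for year in range(1980, 2007)
        ]
        slopes = np.diff(yields)
        assert np.allclose(slopes, cp.tech_slope, atol=1e-12)
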