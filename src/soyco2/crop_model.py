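"""Daily-time-step soybean growth model.

The canopy is a single "big leaf": photosynthesis follows the Farquhar /
von Caemmerer / Berry enzyme-kinetics model evaluated at mean daytime
absorbed PAR, scaled by the Beer's-law absorbed-radiation fraction
``1 - exp(-k * LAI)`` and integrated over daylength.  Soil water is a
single-layer bucket with SCS curve-number runoff and Hargreaves
evapotranspiration demand; drought and cold enter as multiplicative daily
stresses on assimilation.  Yield per cell-year is a harvest-index-like
fraction of final aboveground biomass plus a per-cell linear technology
trend.

Seven parameters (:class:`CalibParams`) are calibrated per grid cell; the
remaining physiology lives in :class:`PhysioConstants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels, solar

__all__ = [
    "WeatherDaily",
    "PhysioConstants",
    "CalibParams",
    "CropState",
    "SeasonResult",
    "SoilFluxes",
    "CellForcing",
    "SimulatedYears",
    "absorbed_par_fraction",
    "arrhenius",
    "farquhar_gross_assimilation",
    "soil_water_step",
    "soil_fluxes",
    "drought_stress",
    "cold_stress",
    "grow_day",
    "simulate_season",
    "simulate_years",
    "simulate_trajectory",
    "initial_state",
    "weather_from_frame",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1
T_REF_K = 298.15

# Activation energies (J mol-1), standard leaf-kinetics values.
EA_VCMAX = 65_330.0
EA_JMAX = 43_540.0
EA_KC = 79_430.0
EA_KO = 36_380.0
EA_GAMMA_STAR = 37_830.0

PAR_FRACTION = 0.48  # PAR fraction of shortwave
UMOL_PER_J = 4.57  # photon content of PAR
G_CH2O_PER_UMOL_CO2 = 30.0e-6  # 44 ug CO2 per umol x 30/44 CH2O:CO2
LATENT_HEAT = 2.45  # MJ kg-1, to convert radiation to mm water


@dataclass
class WeatherDaily:
    """One day of forcing for one grid cell."""

    day_of_year: int
    tmean: float  # degC
    tmin: float  # degC
    tmax: float  # degC
    precip: float  # mm d-1
    srad: float  # MJ m-2 d-1

    def __post_init__(self) -> None:
        if not 1 <= self.day_of_year <= 366:
            raise ValueError(f"day_of_year out of range: {self.day_of_year}")
        if not self.tmin <= self.tmean <= self.tmax:
            raise ValueError(
                f"require tmin <= tmean <= tmax, got "
                f"{self.tmin}/{self.tmean}/{self.tmax}"
            )
        if self.precip < 0 or self.srad < 0:
            raise ValueError("precip and srad must be non-negative")


@dataclass
class PhysioConstants:
    """Fixed physiological and site constants (all overridable).

    Units: vcmax25/jmax25 umol m-2 s-1 at 25 degC; gamma_star25 and kc25 in
    umol mol-1 (ppm); ko25 and o2 in mbar; sla m2 g-1; awc mm; gdd in degC d.
    """

    k_ext: float = 0.5
    vcmax25: float = 100.0
    jmax25: float = 180.0
    gamma_star25: float = 42.75
    kc25: float = 404.9
    ko25: float = 278.4
    o2: float = 210.0
    ci_ratio: float = 0.7
    theta_light: float = 0.9
    phi_q: float = 0.3
    rd_frac: float = 0.015
    sla: float = 0.02
    growth_eff: float = 0.7
    awc: float = 150.0
    gdd_base: float = 10.0
    gdd_maturity: float = 1500.0
    curve_number: float = 75.0
    planting_doy_north: int = 135
    planting_doy_south: int = 315
    leaf_partition: float = 0.5
    leaf_stage_frac: float = 0.6
    init_biomass: float = 5.0  # g m-2 at emergence, all leaf
    init_soil_frac: float = 0.5
    max_season_days: int = 200
    min_season_days: int = 150

    def __post_init__(self) -> None:
        if not 0.0 < self.k_ext <= 1.0:
            raise ValueError("k_ext must be in (0, 1]")
        if not 0.0 < self.ci_ratio < 1.0:
            raise ValueError("ci_ratio must be in (0, 1)")
        for name in (
            "vcmax25",
            "jmax25",
            "gamma_star25",
            "kc25",
            "ko25",
            "o2",
            "theta_light",
            "phi_q",
            "rd_frac",
            "sla",
            "growth_eff",
            "awc",
            "gdd_maturity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def planting_doy(self, hemisphere: str) -> int:
        if hemisphere == "north":
            return self.planting_doy_north
        if hemisphere == "south":
            return self.planting_doy_south
        raise ValueError(f"hemisphere must be 'north' or 'south', got {hemisphere!r}")

    def replace(self, **kwargs) -> "PhysioConstants":
        return replace(self, **kwargs)


@dataclass
class CalibParams:
    """The seven per-cell calibrated parameters.

    co2_sens scales Vcmax25 and Jmax25 jointly and carries the calibrated
    strength of the CO2 response; the technology trend (t/ha, additive) is
    anchored at 1980.
    """

    co2_sens: float = 1.0
    tech_intercept: float = 0.0  # t/ha
    tech_slope: float = 0.0  # t/ha per year
    drought_sens: float = 0.0
    cold_threshold: float = 8.0  # degC
    cold_sens: float = 0.0
    yield_scale: float = 0.35

    def __post_init__(self) -> None:
        if self.co2_sens <= 0:
            raise ValueError("co2_sens must be positive")
        if self.drought_sens < 0 or self.cold_sens < 0:
            raise ValueError("stress sensitivities must be >= 0")
        if not 0.0 < self.yield_scale <= 1.0:
            raise ValueError("yield_scale must be in (0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.co2_sens,
                self.tech_intercept,
                self.tech_slope,
                self.drought_sens,
                self.cold_threshold,
                self.cold_sens,
                self.yield_scale,
            ]
        )

    @classmethod
    def from_array(cls, arr) -> "CalibParams":
        a = np.asarray(arr, dtype=float)
        return cls(
            co2_sens=a[0],
            tech_intercept=a[1],
            tech_slope=a[2],
            drought_sens=a[3],
            cold_threshold=a[4],
            cold_sens=a[5],
            yield_scale=a[6],
        )


PARAM_NAMES = (
    "co2_sens",
    "tech_intercept",
    "tech_slope",
    "drought_sens",
    "cold_threshold",
    "cold_sens",
    "yield_scale",
)


@dataclass
class CropState:
    """Prognostic state of the crop and soil bucket."""

    lai: float
    biomass_above: float
    biomass_leaf: float
    soil_water: float
    gdd_accum: float
    mature: bool


@dataclass
class SeasonResult:
    yield_t_ha: float
    final_biomass: float
    lai_max: float
    stress_days_drought: int
    stress_days_cold: int


@dataclass
class SoilFluxes:
    runoff: float
    infiltration: float
    et_actual: float
    drainage: float
    soil_water: float  # storage after the step


def initial_state(pc: PhysioConstants) -> CropState:
    """Emergence state: all initial biomass is leaf, soil bucket half full."""
    return CropState(
        lai=pc.sla * pc.init_biomass,
        biomass_above=pc.init_biomass,
        biomass_leaf=pc.init_biomass,
        soil_water=pc.init_soil_frac * pc.awc,
        gdd_accum=0.0,
        mature=False,
    )


def absorbed_par_fraction(lai: float, k_ext: float) -> float:
    """Beer's-law fraction of incident PAR absorbed by a canopy of given LAI."""
    if lai < 0:
        raise ValueError(f"lai must be >= 0, got {lai}")
    if k_ext <= 0:
        raise ValueError(f"k_ext must be > 0, got {k_ext}")
    return 1.0 - math.exp(-k_ext * lai)


def arrhenius(t_leaf_c, ea: float):
    """Arrhenius factor relative to 25 degC for activation energy ``ea`` (J/mol)."""
    t_k = np.asarray(t_leaf_c) + 273.15
    return np.exp(ea * (t_k - T_REF_K) / (GAS_CONSTANT * T_REF_K * t_k))


def farquhar_gross_assimilation(
    ca: float,
    tleaf: float,
    par_abs: float,
    pc: PhysioConstants,
    co2_sens: float = 1.0,
) -> float:
    """Net leaf assimilation (umol CO2 m-2 s-1), clipped at zero.

    ``A = min(Ac, Aj) - Rd`` with Rubisco-limited ``Ac`` and RuBP-regeneration
    limited ``Aj`` evaluated at ``Ci = ci_ratio * ca``; the electron transport
    rate J follows a non-rectangular hyperbola in absorbed PAR.  ``co2_sens``
    multiplies Vcmax25 and Jmax25 jointly.
    """
    if ca <= 0:
        raise ValueError("ca must be positive")
    if par_abs < 0:
        raise ValueError("par_abs must be >= 0")
    ci = pc.ci_ratio * ca
    fv = float(arrhenius(tleaf, EA_VCMAX))
    fj = float(arrhenius(tleaf, EA_JMAX))
    kc = pc.kc25 * float(arrhenius(tleaf, EA_KC))
    ko = pc.ko25 * float(arrhenius(tleaf, EA_KO))
    gstar = pc.gamma_star25 * float(arrhenius(tleaf, EA_GAMMA_STAR))
    kmm = kc * (1.0 + pc.o2 / ko)

    vc = co2_sens * pc.vcmax25 * fv
    ac = vc * (ci - gstar) / (ci + kmm)
    jm = co2_sens * pc.jmax25 * fj
    bb = pc.phi_q * par_abs + jm
    disc = max(bb * bb - 4.0 * pc.theta_light * pc.phi_q * par_abs * jm, 0.0)
    j = (bb - math.sqrt(disc)) / (2.0 * pc.theta_light)
    aj = j * (ci - gstar) / (4.0 * ci + 8.0 * gstar)
    a = min(ac, aj) - pc.rd_frac * vc
    return max(a, 0.0)


def _curve_number_runoff(precip: float, cn: float) -> float:
    """SCS curve-number storm runoff (mm) with the 0.2*S initial abstraction."""
    s = 25_400.0 / cn - 254.0
    ia = 0.2 * s
    if precip <= ia:
        return 0.0
    return (precip - ia) ** 2 / (precip + 0.8 * s)


def _hargreaves_et0(w: WeatherDaily, lat: float) -> float:
    """Hargreaves reference evapotranspiration demand (mm d-1)."""
    ra = float(solar.extraterrestrial_radiation(lat, w.day_of_year))
    trange = max(w.tmax - w.tmin, 0.0)
    et0 = 0.0023 * (w.tmean + 17.8) * math.sqrt(trange) * ra / LATENT_HEAT
    return max(et0, 0.0)


def soil_fluxes(
    soil_water: float, w: WeatherDaily, pc: PhysioConstants, lat: float
) -> SoilFluxes:
    """One day of the soil bucket; closes the water balance exactly.

    runoff by curve number, actual ET = Hargreaves demand scaled by relative
    storage, drainage = excess above capacity.
    """
    if not 0.0 <= soil_water <= pc.awc:
        raise ValueError("soil_water outside [0, awc]")
    runoff = _curve_number_runoff(w.precip, pc.curve_number)
    infiltration = w.precip - runoff
    et_actual = _hargreaves_et0(w, lat) * soil_water / pc.awc
    s_mid = soil_water + infiltration - et_actual
    drainage = max(s_mid - pc.awc, 0.0)
    return SoilFluxes(
        runoff=runoff,
        infiltration=infiltration,
        et_actual=et_actual,
        drainage=drainage,
        soil_water=s_mid - drainage,
    )


def soil_water_step(
    state: CropState, w: WeatherDaily, pc: PhysioConstants, lat: float
) -> float:
    """Updated soil storage (mm) after one day of rain, runoff, ET, drainage."""
    return soil_fluxes(state.soil_water, w, pc, lat).soil_water


def drought_stress(soil_water: float, awc: float, drought_sens: float) -> float:
    """Multiplier (s/awc)^drought_sens in [0, 1]; identity when sens = 0."""
    if not 0.0 <= soil_water <= awc:
        raise ValueError("soil_water outside [0, awc]")
    if drought_sens < 0:
        raise ValueError("drought_sens must be >= 0")
    return (soil_water / awc) ** drought_sens


def cold_stress(tmean: float, cold_threshold: float, cold_sens: float) -> float:
    """Multiplier max(0, 1 - cold_sens * shortfall below threshold)."""
    deficit = cold_threshold - tmean
    if deficit <= 0.0:
        return 1.0
    return max(1.0 - cold_sens * deficit, 0.0)


def _daytime_par(w: WeatherDaily, lat: float) -> tuple[float, float]:
    """(mean daytime incident PAR umol m-2 s-1, daylength in seconds)."""
    daylen_s = float(solar.daylength_hours(lat, w.day_of_year)) * 3600.0
    if daylen_s <= 0.0 or w.srad <= 0.0:
        return 0.0, daylen_s
    par = w.srad * 1.0e6 * PAR_FRACTION * UMOL_PER_J / daylen_s
    return par, daylen_s


def grow_day(
    state: CropState,
    w: WeatherDaily,
    ca: float,
    pc: PhysioConstants,
    cp: CalibParams,
    lat: float,
) -> CropState:
    """Advance crop and soil by one day.

    Canopy assimilation = leaf-level Farquhar rate at mean daytime PAR x
    Beer's-law absorbed fraction x daylength x drought and cold multipliers;
    the carbon gain converts to biomass via the CH2O:CO2 molar mass ratio and
    growth efficiency, partitioning half to leaves until the leaf stage ends.
    Growth-degree days accumulate above gdd_base; the soil bucket always steps.
    """
    b_above = state.biomass_above
    b_leaf = state.biomass_leaf
    mature = state.mature or state.gdd_accum >= pc.gdd_maturity
    if not mature:
        par, daylen_s = _daytime_par(w, lat)
        if par > 0.0:
            a_leaf = farquhar_gross_assimilation(ca, w.tmean, par, pc, cp.co2_sens)
            fabs = absorbed_par_fraction(pc.sla * b_leaf, pc.k_ext)
            ds = drought_stress(state.soil_water, pc.awc, cp.drought_sens)
            cs = cold_stress(w.tmean, cp.cold_threshold, cp.cold_sens)
            gain = (
                a_leaf
                * fabs
                * ds
                * cs
                * daylen_s
                * G_CH2O_PER_UMOL_CO2
                * pc.growth_eff
            )
            b_above += gain
            if state.gdd_accum < pc.leaf_stage_frac * pc.gdd_maturity:
                b_leaf += pc.leaf_partition * gain
    gdd = state.gdd_accum + max(w.tmean - pc.gdd_base, 0.0)
    soil = soil_water_step(state, w, pc, lat)
    return CropState(
        lai=pc.sla * b_leaf,
        biomass_above=b_above,
        biomass_leaf=b_leaf,
        soil_water=soil,
        gdd_accum=gdd,
        mature=mature,
    )


def biomass_to_yield(
    final_biomass: float, year: int, cp: CalibParams, base_year: int = 1980
) -> float:
    """t/ha yield: harvest fraction of biomass plus the technology trend."""
    raw = (
        cp.yield_scale * final_biomass * 0.01
        + cp.tech_intercept
        + cp.tech_slope * (year - base_year)
    )
    return max(raw, 0.0)


def simulate_season(
    weather: Sequence[WeatherDaily],
    ca_year: float,
    year: int,
    pc: PhysioConstants,
    cp: CalibParams,
    hemisphere: str,
    lat: float,
) -> SeasonResult:
    """Run one growing season and convert final biomass to yield.

    ``weather`` must contain the planting day for the hemisphere and at least
    ``pc.min_season_days`` days after it; simulation stops at maturity
    (GDD target) or after ``pc.max_season_days`` days.
    """
    pdoy = pc.planting_doy(hemisphere)
    start = next(
        (i for i, w in enumerate(weather) if w.day_of_year == pdoy), None
    )
    if start is None:
        raise ValueError(f"weather does not contain planting day {pdoy}")
    if len(weather) - start < pc.min_season_days:
        raise ValueError(
            f"weather window too short: need >= {pc.min_season_days} days "
            f"from planting, got {len(weather) - start}"
        )
    state = initial_state(pc)
    lai_max = state.lai
    stress_drought = 0
    stress_cold = 0
    n_days = min(pc.max_season_days, len(weather) - start)
    for d in range(n_days):
        w = weather[start + d]
        if state.mature or state.gdd_accum >= pc.gdd_maturity:
            break
        if drought_stress(state.soil_water, pc.awc, cp.drought_sens) < 0.9:
            stress_drought += 1
        if cold_stress(w.tmean, cp.cold_threshold, cp.cold_sens) < 1.0:
            stress_cold += 1
        state = grow_day(state, w, ca_year, pc, cp, lat)
        lai_max = max(lai_max, state.lai)
    return SeasonResult(
        yield_t_ha=biomass_to_yield(state.biomass_above, year, cp),
        final_biomass=state.biomass_above,
        lai_max=lai_max,
        stress_days_drought=stress_drought,
        stress_days_cold=stress_cold,
    )


def weather_from_frame(df: pd.DataFrame) -> list[WeatherDaily]:
    """Convert a weather table (year,doy,tmean,tmin,tmax,precip,srad) to records."""
    return [
        WeatherDaily(
            day_of_year=int(r.doy),
            tmean=float(r.tmean),
            tmin=float(r.tmin),
            tmax=float(r.tmax),
            precip=float(r.precip),
            srad=float(r.srad),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Fast multi-year path


@dataclass
class CellForcing:
    """Per-cell precomputed forcing for the jitted multi-year simulator.

    Everything that does not depend on :class:`CalibParams` (temperature
    kinetics, incident PAR, soil-water trajectory, phenology masks) is frozen
    here, padded to the longest growing window.
    """

    lat: float
    hemisphere: str
    years: np.ndarray
    ndays: np.ndarray
    tmean: np.ndarray
    precip: np.ndarray
    par: np.ndarray
    conv: np.ndarray  # daylength_s * g CH2O per umol CO2
    swr: np.ndarray  # start-of-day soil water / awc
    fv: np.ndarray
    fj: np.ndarray
    kmm: np.ndarray
    gs: np.ndarray
    grow: np.ndarray
    leaf: np.ndarray
    maturity_day: np.ndarray
    pc: PhysioConstants

    @classmethod
    def build(
        cls,
        weather: pd.DataFrame,
        lat: float,
        hemisphere: str,
        years: Sequence[int],
        pc: PhysioConstants,
    ) -> "CellForcing":
        df = weather.sort_values(["year", "doy"]).reset_index(drop=True)
        key = df["year"].to_numpy(np.int64) * 1000 + df["doy"].to_numpy(np.int64)
        wyear = df["year"].to_numpy(np.int64)
        wdoy = df["doy"].to_numpy(np.int64)
        tmean_all = df["tmean"].to_numpy(float)
        tmin_all = df["tmin"].to_numpy(float)
        tmax_all = df["tmax"].to_numpy(float)
        precip_all = df["precip"].to_numpy(float)
        srad_all = df["srad"].to_numpy(float)
        n_rows = len(df)

        pdoy = pc.planting_doy(hemisphere)
        years = np.asarray(list(years), dtype=np.int64)
        starts = []
        lens = []
        for y in years:
            plant_year = int(y) if hemisphere == "north" else int(y) - 1
            k = plant_year * 1000 + pdoy
            i = int(np.searchsorted(key, k))
            if i >= n_rows or key[i] != k:
                raise ValueError(
                    f"weather does not cover planting day {pdoy} of year {plant_year}"
                )
            avail = n_rows - i
            if avail < pc.min_season_days:
                raise ValueError(
                    f"growing window for harvest year {y} too short "
                    f"({avail} < {pc.min_season_days} days)"
                )
            starts.append(i)
            lens.append(min(pc.max_season_days, avail))
        ndays = np.asarray(lens, dtype=np.int64)
        lmax = int(ndays.max())
        n_years = len(years)

        shape = (n_years, lmax)
        tmean2 = np.zeros(shape)
        precip2 = np.zeros(shape)
        par2 = np.zeros(shape)
        conv2 = np.zeros(shape)
        swr2 = np.zeros(shape)
        fv2 = np.zeros(shape)
        fj2 = np.zeros(shape)
        kmm2 = np.zeros(shape)
        gs2 = np.zeros(shape)
        grow2 = np.zeros(shape, dtype=bool)
        leaf2 = np.zeros(shape, dtype=bool)
        maturity_day = np.zeros(n_years, dtype=np.int64)

        for iy, (i0, n) in enumerate(zip(starts, lens)):
            sl = slice(i0, i0 + n)
            tm = tmean_all[sl]
            doy = wdoy[sl]
            tmean2[iy, :n] = tm
            precip2[iy, :n] = precip_all[sl]

            daylen_s = solar.daylength_hours(lat, doy) * 3600.0
            with np.errstate(divide="ignore", invalid="ignore"):
                par = np.where(
                    daylen_s > 0.0,
                    srad_all[sl] * 1.0e6 * PAR_FRACTION * UMOL_PER_J
                    / np.where(daylen_s > 0.0, daylen_s, 1.0),
                    0.0,
                )
            par2[iy, :n] = par
            conv2[iy, :n] = daylen_s * G_CH2O_PER_UMOL_CO2

            fv2[iy, :n] = arrhenius(tm, EA_VCMAX)
            fj2[iy, :n] = arrhenius(tm, EA_JMAX)
            kc = pc.kc25 * arrhenius(tm, EA_KC)
            ko = pc.ko25 * arrhenius(tm, EA_KO)
            kmm2[iy, :n] = kc * (1.0 + pc.o2 / ko)
            gs2[iy, :n] = pc.gamma_star25 * arrhenius(tm, EA_GAMMA_STAR)

            # Soil bucket trajectory (parameter-independent).
            ra = solar.extraterrestrial_radiation(lat, doy)
            trange = np.maximum(tmax_all[sl] - tmin_all[sl], 0.0)
            et0 = np.maximum(
                0.0023 * (tm + 17.8) * np.sqrt(trange) * ra / LATENT_HEAT, 0.0
            )
            runoff = np.array(
                [_curve_number_runoff(p, pc.curve_number) for p in precip_all[sl]]
            )
            infil = precip_all[sl] - runoff
            s = pc.init_soil_frac * pc.awc
            for d in range(n):
                swr2[iy, d] = s / pc.awc
                s_mid = s + infil[d] - et0[d] * s / pc.awc
                s = min(s_mid, pc.awc)

            # Phenology masks from the GDD path (parameter-independent).
            gdd_inc = np.maximum(tm - pc.gdd_base, 0.0)
            gdd_start = np.concatenate(([0.0], np.cumsum(gdd_inc)[:-1]))
            grow2[iy, :n] = gdd_start < pc.gdd_maturity
            leaf2[iy, :n] = gdd_start < pc.leaf_stage_frac * pc.gdd_maturity
            mat = np.nonzero(~grow2[iy, :n])[0]
            maturity_day[iy] = int(mat[0]) if mat.size else n

        return cls(
            lat=lat,
            hemisphere=hemisphere,
            years=years,
            ndays=ndays,
            tmean=tmean2,
            precip=precip2,
            par=par2,
            conv=conv2,
            swr=swr2,
            fv=fv2,
            fj=fj2,
            kmm=kmm2,
            gs=gs2,
            grow=grow2,
            leaf=leaf2,
            maturity_day=maturity_day,
            pc=pc,
        )


@dataclass
class SimulatedYears:
    years: np.ndarray
    yields: np.ndarray  # t/ha
    final_biomass: np.ndarray  # g m-2
    lai_max: np.ndarray


def _ca_by_year(co2, years: np.ndarray) -> np.ndarray:
    if np.isscalar(co2):
        return np.full(len(years), float(co2))
    return np.array([float(co2[int(y)]) for y in years])


def simulate_years(
    forcing: CellForcing,
    co2: "Mapping[int, float] | float",
    cp: CalibParams,
    pc_override: "PhysioConstants | None" = None,
) -> SimulatedYears:
    """Simulate every harvest year of a cell with one parameter set.

    ``co2`` is a year->ppm mapping or a single fixed concentration (the
    counterfactual case).  Deterministic: identical inputs give identical
    output.
    """
    pc = forcing.pc if pc_override is None else pc_override
    ci = pc.ci_ratio * _ca_by_year(co2, forcing.years)
    out_b = np.empty(len(forcing.years))
    out_l = np.empty(len(forcing.years))
    _kernels.run_years(
        forcing.tmean,
        forcing.par,
        forcing.conv,
        forcing.swr,
        forcing.fv,
        forcing.fj,
        forcing.kmm,
        forcing.gs,
        forcing.grow,
        forcing.leaf,
        forcing.ndays,
        ci,
        pc.k_ext,
        pc.sla,
        pc.vcmax25,
        pc.jmax25,
        pc.theta_light,
        pc.phi_q,
        pc.rd_frac,
        pc.growth_eff,
        pc.leaf_partition,
        cp.co2_sens,
        cp.drought_sens,
        cp.cold_threshold,
        cp.cold_sens,
        pc.init_biomass,
        pc.init_biomass,
        out_b,
        out_l,
    )
    yields = np.maximum(
        cp.yield_scale * out_b * 0.01
        + cp.tech_intercept
        + cp.tech_slope * (forcing.years - 1980),
        0.0,
    )
    return SimulatedYears(
        years=forcing.years.copy(),
        yields=yields,
        final_biomass=out_b,
        lai_max=out_l,
    )


def simulate_trajectory(
    forcing: CellForcing,
    year_index: int,
    ca: float,
    cp: CalibParams,
    vcmax25: "float | None" = None,
    jmax25: "float | None" = None,
    sla: "float | None" = None,
    growth_eff: "float | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Daily (aboveground, leaf) biomass for one season; used for FACE fits.

    The four keyword overrides are the physiology dimensions calibrated
    against FACE biomass trajectories.
    """
    pc = forcing.pc
    n = int(forcing.ndays[year_index])
    ta = np.empty(n)
    tl = np.empty(n)
    iy = year_index
    _kernels.run_season(
        forcing.tmean[iy, :n],
        forcing.par[iy, :n],
        forcing.conv[iy, :n],
        forcing.swr[iy, :n],
        forcing.fv[iy, :n],
        forcing.fj[iy, :n],
        forcing.kmm[iy, :n],
        forcing.gs[iy, :n],
        forcing.grow[iy, :n],
        forcing.leaf[iy, :n],
        pc.ci_ratio * ca,
        pc.k_ext,
        pc.sla if sla is None else sla,
        pc.vcmax25 if vcmax25 is None else vcmax25,
        pc.jmax25 if jmax25 is None else jmax25,
        pc.theta_light,
        pc.phi_q,
        pc.rd_frac,
        pc.growth_eff if growth_eff is None else growth_eff,
        pc.leaf_partition,
        cp.co2_sens,
        cp.drought_sens,
        cp.cold_threshold,
        cp.cold_sens,
        pc.init_biomass,
        pc.init_biomass,
        ta,
        tl,
    )
    return ta, tl
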