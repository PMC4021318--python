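"""Synthetic study generator with known ground truth.

Emulates the structure of the real study inputs: per-cell daily weather
(seasonal cycle plus AR(1) anomalies, Bernoulli-Gamma rainfall, clear-sky
radiation damped on rain days), a linear CO2 ramp (339 ppm in 1980 to
377 ppm in 2006), county-style yield series produced by the crop model under
known per-cell parameters plus Gaussian noise and a linear technology trend,
and paired ambient/elevated FACE biomass trajectories.  Aridity varies
across the cells of each country so the P:PET axis of the downstream
statistics has spread.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .calibration import FaceObservation
from .crop_model import (
    CalibParams,
    CellForcing,
    PhysioConstants,
    simulate_trajectory,
    simulate_years,
)
from .data_io import CellRecord

__all__ = [
    "SynthConfig",
    "CellSpec",
    "StudyData",
    "gen_weather",
    "gen_co2",
    "gen_cell_yields",
    "gen_face",
    "generate_study",
    "write_study",
    "default_cell_specs",
    "draw_true_params",
]


@dataclass
class CellSpec:
    """Climate archetype of one synthetic cell."""

    cell_id: str
    country: str
    lat: float
    lon: float
    tmean_ann: float  # degC annual mean
    tamp: float  # degC seasonal half-amplitude
    peak_doy: int  # day of warmest day
    wet_prob: float  # wet-day probability
    wet_mean: float  # mean rainfall on wet days, mm
    aridity: float  # multiplier on rainfall amounts (dry < 1 < wet)

    @property
    def hemisphere(self) -> str:
        return "north" if self.lat >= 0 else "south"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic grid.

    Defaults follow the historical setting: 1980-2006, CO2 ramping from
    339 ppm to 377 ppm, yield observation noise of 0.3 t/ha.
    """

    n_cells_per_country: int = 2
    year_start: int = 1980
    year_end: int = 2006
    seed: int = 0
    co2_start: float = 339.0
    co2_end: float = 377.0
    noise_sd: float = 0.3
    harvest_area_fraction: float = 0.05
    ar1_rho: float = 0.7
    ar1_sd: float = 1.5
    yearly_temp_sd: float = 0.5
    yearly_precip_log_sd: float = 0.3
    countries: tuple = ("USA", "Brazil", "China")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def _stable_id(cell_id: str) -> int:
    """Process-independent integer tag for per-cell RNG streams."""
    return zlib.crc32(cell_id.encode()) % 100_000


def _grid_snap(v: float) -> float:
    """Snap a coordinate to the 1.125 degree grid."""
    return round(round(v / 1.125) * 1.125, 4)


_COUNTRY_ARCHETYPES = {
    # (lat range, lon range, tmean_ann, tamp, peak doy, wet prob, wet mean)
    "USA": ((36.0, 45.0), (-103.0, -82.0), (9.0, 14.0), (11.0, 14.0), 200, 0.35, 6.0),
    "Brazil": ((-28.0, -12.0), (-60.0, -45.0), (21.0, 25.0), (3.0, 6.0), 15, 0.45, 8.0),
    "China": ((32.0, 46.0), (110.0, 130.0), (7.0, 13.0), (13.0, 16.0), 200, 0.30, 6.0),
}


def default_cell_specs(cfg: SynthConfig) -> list[CellSpec]:
    """One archetype per cell, aridity spread evenly within each country."""
    rng = np.random.default_rng(cfg.seed)
    specs = []
    n = cfg.n_cells_per_country
    for country in cfg.countries:
        (lat_r, lon_r, tm_r, ta_r, peak, wp, wm) = _COUNTRY_ARCHETYPES[country]
        aridity = np.linspace(0.45, 1.4, n) if n > 1 else np.array([0.9])
        for i in range(n):
            specs.append(
                CellSpec(
                    cell_id=f"{country[:2].upper()}{i:03d}",
                    country=country,
                    lat=_grid_snap(rng.uniform(*lat_r)),
                    lon=_grid_snap(rng.uniform(*lon_r)),
                    tmean_ann=float(rng.uniform(*tm_r)),
                    tamp=float(rng.uniform(*ta_r)),
                    peak_doy=peak,
                    wet_prob=wp,
                    wet_mean=wm,
                    aridity=float(aridity[i]),
                )
            )
    return specs


def draw_true_params(rng: np.random.Generator) -> CalibParams:
    """Realistic ground-truth parameters, inside the calibration priors."""
    return CalibParams(
        co2_sens=float(rng.lognormal(0.0, 0.15)),
        tech_intercept=float(rng.uniform(-0.3, 0.8)),
        tech_slope=float(np.clip(rng.normal(0.02, 0.01), 0.0, 0.05)),
        drought_sens=float(rng.uniform(0.2, 1.5)),
        cold_threshold=float(rng.uniform(4.0, 10.0)),
        cold_sens=float(rng.uniform(0.0, 0.2)),
        yield_scale=float(rng.uniform(0.2, 0.5)),
    )


def gen_weather(cfg: SynthConfig, cell: CellSpec, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Daily weather from the year before the study start through its end.

    Sinusoidal seasonal temperature with AR(1) daily and Gaussian yearly
    anomalies; Bernoulli-Gamma rainfall scaled by the cell's aridity and a
    lognormal yearly wetness factor; radiation = clear-sky top-of-atmosphere
    times a transmissivity reduced on rain days.  365-day years.
    """
    from . import solar

    if rng is None:
        rng = np.random.default_rng(cfg.seed + _stable_id(cell.cell_id))
    years = np.arange(cfg.year_start - 1, cfg.year_end + 1)
    n_years = len(years)
    doy = np.tile(np.arange(1, 366), n_years)
    year_col = np.repeat(years, 365)
    n = doy.size

    seasonal = cell.tmean_ann + cell.tamp * np.cos(
        2.0 * np.pi * (doy - cell.peak_doy) / 365.0
    )
    anom = lfilter([1.0], [1.0, -cfg.ar1_rho], rng.normal(0.0, cfg.ar1_sd, size=n))
    year_offset = np.repeat(rng.normal(0.0, cfg.yearly_temp_sd, size=n_years), 365)
    tmean = seasonal + anom + year_offset
    dtr = np.clip(rng.normal(9.0, 1.5, size=n), 3.0, None)
    tmin = tmean - dtr / 2.0
    tmax = tmean + dtr / 2.0

    # Rainfall: wetter in the warm season, dry-to-wet gradient across cells.
    season_factor = 0.6 + 0.8 * (seasonal - seasonal.min()) / max(
        seasonal.max() - seasonal.min(), 1e-9
    )
    wet = rng.random(n) < np.clip(cell.wet_prob * season_factor, 0.02, 0.95)
    amounts = rng.gamma(0.7, cell.wet_mean / 0.7, size=n)
    year_wetness = np.repeat(
        rng.lognormal(0.0, cfg.yearly_precip_log_sd, size=n_years), 365
    )
    precip = np.where(wet, amounts * cell.aridity * year_wetness, 0.0)

    ra = solar.extraterrestrial_radiation(cell.lat, doy)
    tau = np.where(wet, 0.40, 0.70) + rng.normal(0.0, 0.05, size=n)
    srad = np.maximum(ra * np.clip(tau, 0.1, 0.8), 0.0)

    return pd.DataFrame(
        {
            "year": year_col,
            "doy": doy,
            "tmean": tmean,
            "tmin": tmin,
            "tmax": tmax,
            "precip": precip,
            "srad": srad,
        }
    )


def gen_co2(cfg: SynthConfig) -> dict:
    """Linear CO2 ramp over the study years, {year: ppm}."""
    years = cfg.years
    span = max(len(years) - 1, 1)
    return {
        int(y): cfg.co2_start + (cfg.co2_end - cfg.co2_start) * i / span
        for i, y in enumerate(years)
    }


def gen_cell_yields(
    cfg: SynthConfig,
    cell: CellSpec,
    pc: PhysioConstants,
    true_cp: CalibParams,
    weather: Optional[pd.DataFrame] = None,
    missing_years: Sequence[int] = (),
    rng: Optional[np.random.Generator] = None,
) -> CellRecord:
    """Yield series from the crop model under known parameters plus noise."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7919 + _stable_id(cell.cell_id))
    if weather is None:
        weather = gen_weather(cfg, cell, rng=rng)
    co2 = gen_co2(cfg)
    forcing = CellForcing.build(weather, cell.lat, cell.hemisphere, cfg.years, pc)
    sim = simulate_years(forcing, co2, true_cp)
    noisy = np.maximum(sim.yields + rng.normal(0.0, cfg.noise_sd, size=len(sim.years)), 0.0)
    yields = {
        int(y): float(v)
        for y, v in zip(sim.years, noisy)
        if int(y) not in set(int(m) for m in missing_years)
    }
    return CellRecord(
        cell_id=cell.cell_id,
        lat=cell.lat,
        lon=cell.lon,
        country=cell.country,
        yields=yields,
        harvest_area_fraction=cfg.harvest_area_fraction,
        weather=weather,
    )


FACE_AMBIENT_PPM = 372.0
FACE_ELEVATED_PPM = 552.0


def gen_face(
    cfg: SynthConfig,
    pc: PhysioConstants,
    lat: float = 40.5,
    obs_interval: int = 14,
    obs_noise_frac: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[FaceObservation], pd.DataFrame, float]:
    """Paired ambient/elevated biomass time courses from the crop model.

    Returns (observations, single-season weather table, latitude).  The
    elevated treatment adds ~180 ppm over ambient, as in field FACE studies.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 424_243)
    spec = CellSpec(
        cell_id="FACE",
        country="USA",
        lat=lat,
        lon=-88.875,
        tmean_ann=11.5,
        tamp=12.5,
        peak_doy=200,
        wet_prob=0.4,
        wet_mean=7.0,
        aridity=1.2,
    )
    one_year = replace(cfg, year_start=2000, year_end=2000)
    weather = gen_weather(one_year, spec, rng=rng)
    weather = weather[weather["year"] == 2000].reset_index(drop=True)
    forcing = CellForcing.build(weather, lat, "north", [2000], pc)
    cp = CalibParams()  # well-watered, stress-free plot
    n_days = int(forcing.ndays[0])
    obs: list[FaceObservation] = []
    for ca in (FACE_AMBIENT_PPM, FACE_ELEVATED_PPM):
        ta, tl = simulate_trajectory(forcing, 0, ca, cp)
        for day in range(obs_interval, n_days + 1, obs_interval):
            above_true = float(ta[day - 1])
            leaf_true = float(tl[day - 1])
            # reported uncertainty is floored; sampling noise follows the frac
            sd = max(obs_noise_frac * above_true, 5.0)
            noise = obs_noise_frac * above_true
            above = max(above_true + rng.normal(0.0, noise), 0.0)
            leaf = min(max(leaf_true + rng.normal(0.0, noise), 0.0), above)
            obs.append(
                FaceObservation(
                    day=day,
                    co2_treatment=ca,
                    aboveground_biomass=above,
                    leaf_biomass=leaf,
                    sd=sd,
                )
            )
    return obs, weather, lat


@dataclass
class StudyData:
    """A complete synthetic study with its generating truth."""

    cells: list  # CellRecord, weather attached
    co2: dict  # year -> ppm
    truths: dict  # cell_id -> CalibParams
    specs: list = field(default_factory=list)
    face: Optional[tuple] = None  # (observations, weather, lat)


def generate_study(
    cfg: SynthConfig,
    pc: Optional[PhysioConstants] = None,
    specs: Optional[Sequence[CellSpec]] = None,
    with_face: bool = True,
) -> StudyData:
    """Generate every input the pipeline needs, with known ground truth."""
    pc = pc or PhysioConstants()
    specs = list(specs) if specs is not None else default_cell_specs(cfg)
    rng = np.random.default_rng(cfg.seed)
    cells, truths = [], {}
    for spec in specs:
        truth = draw_true_params(rng)
        cell_rng = np.random.default_rng(rng.integers(2**31))
        rec = gen_cell_yields(cfg, spec, pc, truth, rng=cell_rng)
        cells.append(rec)
        truths[spec.cell_id] = truth
    face = gen_face(cfg, pc, rng=np.random.default_rng(rng.integers(2**31))) if with_face else None
    return StudyData(cells=cells, co2=gen_co2(cfg), truths=truths, specs=specs, face=face)


def write_study(study: StudyData, out_dir) -> None:
    """Emit the CSV dialects consumed by data_io and calibration."""
    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "lat": c.lat,
                "lon": c.lon,
                "country": c.country,
                "area_fraction": c.harvest_area_fraction,
            }
            for c in study.cells
        ]
    ).to_csv(os.path.join(out_dir, "cells.csv"), index=False)
    pd.DataFrame(
        [
            {"cell_id": c.cell_id, "year": y, "yield_t_ha": v}
            for c in study.cells
            for y, v in sorted(c.yields.items())
        ]
    ).to_csv(os.path.join(out_dir, "yields.csv"), index=False)
    pd.DataFrame(
        {"year": list(study.co2), "co2_ppm": list(study.co2.values())}
    ).to_csv(os.path.join(out_dir, "co2.csv"), index=False)
    for c in study.cells:
        c.weather.to_csv(os.path.join(out_dir, f"weather_{c.cell_id}.csv"), index=False)
    pd.DataFrame(
        [
            {
                "cell_id": cid,
                **{k: getattr(cp, k) for k in (
                    "co2_sens", "tech_intercept", "tech_slope", "drought_sens",
                    "cold_threshold", "cold_sens", "yield_scale",
                )},
            }
            for cid, cp in study.truths.items()
        ]
    ).to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    if study.face is not None:
        obs, weather, lat = study.face
        pd.DataFrame(
            [
                {
                    "day": o.day,
                    "co2_ppm": o.co2_treatment,
                    "aboveground_g_m2": o.aboveground_biomass,
                    "leaf_g_m2": o.leaf_biomass,
                    "sd": o.sd,
                }
                for o in obs
            ]
        ).to_csv(os.path.join(out_dir, "face.csv"), index=False)
        weather.to_csv(os.path.join(out_dir, "weather_FACE.csv"), index=False)
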