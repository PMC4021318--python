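"""Reading and aggregating yield, harvest-area, weather and CO2 inputs.

County yields are averaged (unweighted by default) into 1.125 degree grid
cells; cells enter the analysis only if they hold more than 1% of the
national soybean harvest area and have more than 14 years of yield data
with no gap longer than 3 consecutive missing years.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "aggregate_county_yields",
    "cell_filter",
    "longest_missing_run",
    "read_weather_csv",
    "read_co2_csv",
    "read_yield_table",
    "read_county_table",
    "read_area_table",
    "load_study",
]

COUNTRIES = ("USA", "Brazil", "China")


@dataclass
class CellRecord:
    """One 1.125 degree grid cell: metadata, yield series, forcing handle."""

    cell_id: str
    lat: float
    lon: float
    country: str
    yields: dict  # year -> t/ha; missing years are absent keys, never 0
    harvest_area_fraction: float
    weather: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.country not in COUNTRIES:
            raise ValueError(f"unknown country {self.country!r}")
        if not 0.0 <= self.harvest_area_fraction <= 1.0:
            raise ValueError("harvest_area_fraction must be in [0, 1]")

    @property
    def hemisphere(self) -> str:
        return "north" if self.lat >= 0 else "south"

    @property
    def years(self) -> np.ndarray:
        return np.array(sorted(self.yields), dtype=np.int64)


def aggregate_county_yields(
    county_series: Sequence[Mapping[int, float]],
    weights: Optional[Sequence[float]] = None,
) -> dict:
    """Per-year mean yield over the counties reporting that year.

    Unweighted by default; optional ``weights`` (e.g. harvested areas) give a
    weighted mean over the reporting counties.
    """
    if len(county_series) == 0:
        raise ValueError("need at least one county series")
    if weights is not None and len(weights) != len(county_series):
        raise ValueError("weights must match the number of county series")
    out: dict[int, float] = {}
    years = sorted({y for s in county_series for y in s})
    for y in years:
        vals, wts = [], []
        for i, s in enumerate(county_series):
            if y in s:
                vals.append(float(s[y]))
                wts.append(1.0 if weights is None else float(weights[i]))
        out[y] = float(np.average(vals, weights=wts))
    return out


def longest_missing_run(years_present: Sequence[int]) -> int:
    """Longest run of consecutive missing years inside the observed span.

    Gaps before the first and after the last observation do not count.
    """
    ys = sorted(set(int(y) for y in years_present))
    if len(ys) < 2:
        return 0
    return max(b - a - 1 for a, b in zip(ys[:-1], ys[1:]))


def cell_filter(
    rec: CellRecord,
    min_area_fraction: float = 0.01,
    min_years: int = 14,
    max_gap: int = 3,
) -> bool:
    """Eligibility: area share > 1%, > 14 observed years, gaps of <= 3 years."""
    if rec.harvest_area_fraction <= min_area_fraction:
        return False
    if len(rec.yields) <= min_years:
        return False
    return longest_missing_run(list(rec.yields)) <= max_gap


# ---------------------------------------------------------------------------
# CSV dialects

WEATHER_COLUMNS = ["year", "doy", "tmean", "tmin", "tmax", "precip", "srad"]


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather file {path} lacks columns {sorted(missing)}")
    return df[WEATHER_COLUMNS]


def read_co2_csv(path) -> dict:
    """CO2 series CSV (year,co2_ppm) -> {year: ppm}."""
    df = pd.read_csv(path)
    return dict(zip(df["year"].astype(int), df["co2_ppm"].astype(float)))


def read_yield_table(path) -> dict:
    """Cell yield CSV (cell_id,year,yield_t_ha) -> {cell_id: {year: t/ha}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[int, float]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.cell_id), {})[int(r.year)] = float(r.yield_t_ha)
    return out


def read_county_table(path) -> dict:
    """County CSV (cell_id,county_id,year,yield_t_ha) -> per-cell county series."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, dict[int, float]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.cell_id), {}).setdefault(str(r.county_id), {})[
            int(r.year)
        ] = float(r.yield_t_ha)
    return out


def read_area_table(path) -> dict:
    """Harvest-area CSV (cell_id,area_fraction) -> {cell_id: fraction}."""
    df = pd.read_csv(path)
    return dict(zip(df["cell_id"].astype(str), df["area_fraction"].astype(float)))


def load_study(directory) -> tuple[list[CellRecord], dict]:
    """Load a study directory written by the synthetic generator or a user.

    Expects cells.csv (cell_id,lat,lon,country,area_fraction), yields.csv,
    co2.csv and one weather_<cell_id>.csv per cell.  Returns the cell records
    (with weather attached) and the CO2 series.
    """
    cells_df = pd.read_csv(os.path.join(directory, "cells.csv"))
    yields = read_yield_table(os.path.join(directory, "yields.csv"))
    co2 = read_co2_csv(os.path.join(directory, "co2.csv"))
    records = []
    for r in cells_df.itertuples():
        cid = str(r.cell_id)
        weather = read_weather_csv(os.path.join(directory, f"weather_{cid}.csv"))
        records.append(
            CellRecord(
                cell_id=cid,
                lat=float(r.lat),
                lon=float(r.lon),
                country=str(r.country),
                yields=yields.get(cid, {}),
                harvest_area_fraction=float(r.area_fraction),
                weather=weather,
            )
        )
    return records, co2
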