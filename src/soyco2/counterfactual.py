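"""Counterfactual attribution of the CO2 fertilization effect.

For every retained posterior draw the cell is simulated twice over an
evaluation window (default 2002-2006): once under the historical CO2
trajectory and once with CO2 fixed at its 1980 level.  Weather, parameters
and the technology trend are identical in both runs, so the paired yield
difference isolates the direct CO2 effect; climate-trend effects are
obtained the same way by linearly detrending one forcing variable instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .crop_model import CalibParams, CellForcing, PhysioConstants, simulate_years
from .calibration import PosteriorSample
from .data_io import CellRecord

__all__ = [
    "EffectEstimate",
    "co2_effect_cell",
    "detrend_climate",
    "detrend_weather_variable",
    "climate_trend_effect_cell",
    "country_average",
]

CLIMATE_VARIABLES = {
    "temperature": ("tmean", "tmin", "tmax"),
    "precipitation": ("precip",),
    "radiation": ("srad",),
}


@dataclass
class EffectEstimate:
    """Per-cell counterfactual yield difference over the evaluation window."""

    cell_id: str
    effect_t_ha: float
    effect_pct: float  # relative to the counterfactual-window mean yield
    posterior_sd_t_ha: float
    window: tuple  # (first year, last year)


def _window_years(years: np.ndarray, window: tuple) -> np.ndarray:
    lo, hi = int(window[0]), int(window[1])
    idx = np.nonzero((years >= lo) & (years <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"window {window} contains no simulated years")
    return idx


def _paired_effect(
    forcing_hist: CellForcing,
    forcing_cf: CellForcing,
    co2_hist,
    co2_cf,
    post: PosteriorSample,
    window: tuple,
    max_draws: int,
    pct_base: str,
) -> tuple[float, float, float]:
    idx = _window_years(forcing_hist.years, window)
    draws = post.thin(max_draws)
    diffs = np.empty(len(draws))
    bases = np.empty(len(draws))
    facts = np.empty(len(draws))
    for i, theta in enumerate(draws):
        cp = CalibParams.from_array(theta[:7])
        y_hist = simulate_years(forcing_hist, co2_hist, cp).yields[idx]
        y_cf = simulate_years(forcing_cf, co2_cf, cp).yields[idx]
        diffs[i] = float(np.mean(y_hist - y_cf))
        bases[i] = float(np.mean(y_cf))
        facts[i] = float(np.mean(y_hist))
    effect = float(diffs.mean())
    base = float(bases.mean()) if pct_base == "counterfactual" else float(facts.mean())
    pct = 100.0 * effect / base if base > 0 else float("nan")
    return effect, pct, float(diffs.std(ddof=1)) if len(draws) > 1 else 0.0


def co2_effect_cell(
    rec: CellRecord,
    post: PosteriorSample,
    pc: PhysioConstants,
    co2_hist: Mapping[int, float],
    co2_fixed: float = 339.0,
    window: tuple = (2002, 2006),
    max_draws: int = 200,
    pct_base: str = "counterfactual",
) -> EffectEstimate:
    """CO2 fertilization effect for one cell from its posterior sample.

    Deterministic given the posterior: draws are subsampled on an even grid,
    and both simulations share weather and technology terms exactly.
    ``pct_base`` selects the denominator of the percentage ("counterfactual",
    the default, or "factual").
    """
    if post.n_retained == 0:
        raise ValueError("empty posterior sample")
    years = rec.years
    forcing = CellForcing.build(rec.weather, rec.lat, rec.hemisphere, years, pc)
    effect, pct, sd = _paired_effect(
        forcing, forcing, co2_hist, float(co2_fixed), post, window, max_draws, pct_base
    )
    return EffectEstimate(
        cell_id=rec.cell_id,
        effect_t_ha=effect,
        effect_pct=pct,
        posterior_sd_t_ha=sd,
        window=(int(window[0]), int(window[1])),
    )


def detrend_climate(
    series: Mapping[int, float], years: Optional[Sequence[int]] = None,
    base_year: int = 1980,
) -> dict:
    """Remove the OLS linear trend from an annual series, anchored at 1980.

    value'(y) = value(y) - b * (y - base_year) with b the least-squares slope.
    """
    ys = np.array(sorted(series) if years is None else sorted(years), dtype=float)
    if ys.size < 3:
        raise ValueError("need at least 3 years to estimate a trend")
    vals = np.array([series[int(y)] for y in ys])
    slope = float(np.polyfit(ys, vals, 1)[0])
    return {int(y): float(series[int(y)] - slope * (y - base_year)) for y in ys}


def detrend_weather_variable(
    weather: pd.DataFrame,
    variable: str,
    season_mask: Optional[pd.Series] = None,
    base_year: int = 1980,
) -> pd.DataFrame:
    """Detrend one forcing variable in a daily weather table.

    The trend is the OLS slope of the growing-season annual mean (all days if
    no season mask is given); the per-year offset ``b * (y - 1980)`` is then
    subtracted from the daily values.  Precipitation and radiation are floored
    at zero; temperature shifts tmean, tmin and tmax together.
    """
    if variable not in CLIMATE_VARIABLES:
        raise ValueError(f"variable must be one of {sorted(CLIMATE_VARIABLES)}")
    cols = CLIMATE_VARIABLES[variable]
    df = weather.copy()
    sub = df if season_mask is None else df[season_mask]
    annual = sub.groupby("year")[cols[0]].mean()
    if len(annual) < 3:
        raise ValueError("need at least 3 years to estimate a trend")
    slope = float(np.polyfit(annual.index.to_numpy(float), annual.to_numpy(), 1)[0])
    offset = slope * (df["year"].to_numpy(float) - base_year)
    for c in cols:
        vals = df[c].to_numpy(float) - offset
        if variable in ("precipitation", "radiation"):
            vals = np.maximum(vals, 0.0)
        df[c] = vals
    return df


def climate_trend_effect_cell(
    rec: CellRecord,
    post: PosteriorSample,
    pc: PhysioConstants,
    variable: str,
    co2_hist: Mapping[int, float],
    window: tuple = (2002, 2006),
    max_draws: int = 200,
    pct_base: str = "counterfactual",
) -> EffectEstimate:
    """Effect of the historical trend in one climate variable on yield.

    The counterfactual re-simulation uses the same CO2 trajectory but the
    chosen forcing variable linearly detrended to its 1980 level.
    """
    years = rec.years
    forcing_hist = CellForcing.build(rec.weather, rec.lat, rec.hemisphere, years, pc)
    weather_cf = detrend_weather_variable(rec.weather, variable)
    forcing_cf = CellForcing.build(weather_cf, rec.lat, rec.hemisphere, years, pc)
    effect, pct, sd = _paired_effect(
        forcing_hist, forcing_cf, co2_hist, co2_hist, post, window, max_draws, pct_base
    )
    return EffectEstimate(
        cell_id=rec.cell_id,
        effect_t_ha=effect,
        effect_pct=pct,
        posterior_sd_t_ha=sd,
        window=(int(window[0]), int(window[1])),
    )


def write_effects(effects: Sequence[EffectEstimate], path) -> None:
    """Per-cell effect table CSV."""
    pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "effect_t_ha": e.effect_t_ha,
                "effect_pct": e.effect_pct,
                "posterior_sd": e.posterior_sd_t_ha,
                "window_start": e.window[0],
                "window_end": e.window[1],
            }
            for e in effects
        ]
    ).to_csv(path, index=False)


def country_average(
    effects: Sequence[EffectEstimate],
    cells: Sequence[CellRecord],
    country: str,
    weights: Optional[Mapping[str, float]] = None,
) -> tuple[float, float]:
    """(t/ha, %) mean effect over a country's cells; unweighted by default."""
    by_id = {c.cell_id: c for c in cells}
    rows = [e for e in effects if by_id[e.cell_id].country == country]
    if not rows:
        raise ValueError(f"no cells for country {country!r}")
    w = np.array([1.0 if weights is None else float(weights[e.cell_id]) for e in rows])
    t_ha = float(np.average([e.effect_t_ha for e in rows], weights=w))
    pct = float(np.average([e.effect_pct for e in rows], weights=w))
    return t_ha, pct
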