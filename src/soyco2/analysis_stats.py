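"""Spatial statistics on the per-cell CO2 fertilization effects.

Thornthwaite potential evapotranspiration and the growing-season P:PET
dryness index, Kendall rank correlations of the effect against environmental
covariates, and AIC selection among three piecewise-linear models of effect
versus P:PET (a plain line; two intersecting sloped lines; a flat segment
meeting a sloped one) to locate the dryness threshold where the effect
starts to grow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import solar

__all__ = [
    "PiecewiseFit",
    "thornthwaite_pet",
    "p_pet_ratio",
    "growing_season_p_pet",
    "kendall_tau",
    "fit_piecewise",
    "select_model",
    "linear_face_extrapolation",
]

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_MID_DOY = np.array([16, 45, 75, 105, 136, 166, 197, 228, 258, 289, 319, 350])


def thornthwaite_pet(
    monthly_tmean: Sequence[float], lat: float, daylength_correction: bool = True
) -> np.ndarray:
    """Monthly potential evapotranspiration (mm month-1), Thornthwaite style.

    Heat index I = sum over months of max(0, T/5)^1.514; the uncorrected
    monthly PET 16 (10 T / I)^a is scaled by the daylength / month-length
    factor (L/12)(N/30) unless ``daylength_correction`` is off.  Months at or
    below 0 degC evaporate nothing.
    """
    t = np.asarray(monthly_tmean, dtype=float)
    if t.shape != (12,):
        raise ValueError("monthly_tmean must have exactly 12 values")
    heat = float(np.sum(np.maximum(t / 5.0, 0.0) ** 1.514))
    if heat <= 0.0:
        return np.zeros(12)
    a = (
        6.75e-7 * heat**3
        - 7.71e-5 * heat**2
        + 1.792e-2 * heat
        + 0.49239
    )
    pet = 16.0 * (10.0 * np.maximum(t, 0.0) / heat) ** a
    if not daylength_correction:
        return pet
    daylen = solar.daylength_hours(lat, MONTH_MID_DOY)
    return pet * (daylen / 12.0) * (MONTH_DAYS / 30.0)


def p_pet_ratio(precip_season: float, pet_season: float) -> float:
    """Growing-season precipitation over potential evapotranspiration."""
    if pet_season <= 0:
        raise ValueError("pet_season must be positive")
    if precip_season < 0:
        raise ValueError("precip_season must be non-negative")
    return precip_season / pet_season


def growing_season_p_pet(
    weather: pd.DataFrame,
    lat: float,
    planting_doy: int,
    season_days: int = 150,
) -> float:
    """Mean over years of growing-season P:PET for one cell.

    Monthly Thornthwaite PET is spread uniformly over each month's days, then
    precipitation and PET are summed over the window starting at planting.
    """
    df = weather.sort_values(["year", "doy"]).reset_index(drop=True)
    month_of_doy = np.searchsorted(np.cumsum(MONTH_DAYS), np.minimum(df["doy"], 365),
                                   side="left")
    df = df.assign(month=month_of_doy)
    pet_daily = np.empty(len(df))
    for year, sub in df.groupby("year"):
        tmon = sub.groupby("month")["tmean"].mean()
        monthly = np.array([tmon.get(m, 10.0) for m in range(12)])
        pet = thornthwaite_pet(monthly, lat)
        pet_daily[sub.index] = pet[sub["month"]] / MONTH_DAYS[sub["month"]]
    precip = df["precip"].to_numpy(float)
    starts = np.nonzero(df["doy"].to_numpy() == planting_doy)[0]
    ratios = []
    for i0 in starts:
        if i0 + season_days > len(df):
            continue
        sl = slice(i0, i0 + season_days)
        ratios.append(p_pet_ratio(float(precip[sl].sum()), float(pet_daily[sl].sum())))
    if not ratios:
        raise ValueError("no complete growing season in the weather table")
    return float(np.mean(ratios))


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b and its two-sided p-value.

    Exact enumeration p for n <= 8 without ties, otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    no_ties = len(np.unique(x)) == x.size and len(np.unique(y)) == y.size
    method = "exact" if (x.size <= 8 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PiecewiseFit:
    """A fitted candidate model of effect versus P:PET."""

    model_id: int
    params: dict
    rss: float
    n: int
    k: int  # free parameters, error variance included
    aic: float
    breakpoint: Optional[float] = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model_id == 1:
            return p["intercept"] + p["slope"] * x
        hinge = np.maximum(x - self.breakpoint, 0.0)
        if self.model_id == 2:
            return p["intercept"] + p["slope_left"] * x + p["slope_change"] * hinge
        return p["intercept"] + p["slope_right"] * hinge


def _aic(rss: float, n: int, k: int, y_scale: float = 1.0) -> float:
    # Floor the RSS near the double-precision resolution of the response so
    # that exact fits (rss ~ 1e-28 from rounding) compare as ties, not as
    # astronomically different log terms.
    floor = n * (1e-9 * max(y_scale, 1e-12)) ** 2
    return n * math.log(max(rss, floor) / n) + 2 * k


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def _breakpoint_grid(x: np.ndarray) -> np.ndarray:
    """Candidate breakpoints: observed x below the maximum plus an equispaced
    interior grid; including min(x) lets models 2/3 degenerate to a plain line,
    which keeps the model classes nested."""
    xs = np.unique(x)
    grid = np.concatenate([xs[:-1], np.linspace(xs[0], xs[-1], 102)[:-1]])
    return np.unique(grid)


def fit_piecewise(x: Sequence[float], y: Sequence[float], model_id: int) -> PiecewiseFit:
    """Least-squares fit of one of the three candidate effect-P:PET models.

    Model 1 is a plain line; models 2 and 3 are continuous two-segment lines
    with the breakpoint profiled over a grid (model 3 forces the left slope to
    zero).  Ties in RSS go to the smallest breakpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    k = {1: 3, 2: 5, 3: 4}.get(model_id)
    if k is None:
        raise ValueError("model_id must be 1, 2 or 3")
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} points for model {model_id}")

    y_scale = float(np.sqrt(np.mean(y**2)))
    if model_id == 1:
        beta, rss = _ols(np.column_stack([np.ones(n), x]), y)
        return PiecewiseFit(
            model_id=1,
            params={"intercept": float(beta[0]), "slope": float(beta[1])},
            rss=rss,
            n=n,
            k=k,
            aic=_aic(rss, n, k, y_scale),
        )

    best = None
    for c in _breakpoint_grid(x):
        hinge = np.maximum(x - c, 0.0)
        if model_id == 2:
            design = np.column_stack([np.ones(n), x, hinge])
        else:
            design = np.column_stack([np.ones(n), hinge])
        beta, rss = _ols(design, y)
        if best is None or rss < best[1]:
            best = (float(c), rss, beta)
    c, rss, beta = best
    if model_id == 2:
        params = {
            "intercept": float(beta[0]),
            "slope_left": float(beta[1]),
            "slope_change": float(beta[2]),
            "slope_right": float(beta[1] + beta[2]),
        }
    else:
        params = {"intercept": float(beta[0]), "slope_right": float(beta[1])}
    return PiecewiseFit(
        model_id=model_id,
        params=params,
        rss=rss,
        n=n,
        k=k,
        aic=_aic(rss, n, k, y_scale),
        breakpoint=c,
    )


def select_model(fits: Sequence[PiecewiseFit], tie_tol: float = 2.0) -> int:
    """Model id with the lowest AIC.

    Models within ``tie_tol`` AIC units of the minimum are treated as
    equivalently supported (the usual "delta AIC < 2" reading) and the most
    parsimonious of them wins; set ``tie_tol=0`` for a strict argmin.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    best = min(f.aic for f in fits)
    contenders = [f for f in fits if f.aic <= best + tie_tol]
    order = sorted(contenders, key=lambda f: (f.k, f.aic, f.model_id))
    return order[0].model_id


def linear_face_extrapolation(
    face_gain_pct: float, face_delta_ppm: float, delta_ppm: float
) -> float:
    """Scale a FACE yield gain linearly to a different CO2 increment."""
    if face_delta_ppm <= 0:
        raise ValueError("face_delta_ppm must be positive")
    return face_gain_pct * delta_ppm / face_delta_ppm
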