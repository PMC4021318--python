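"""Numba kernels for the daily crop-growth loop.

These mirror, operation for operation, the scalar path in
:mod:`soyco2.crop_model` (``grow_day``/``simulate_season``); a test asserts
the two paths agree.  All per-day quantities that do not depend on the
calibrated parameters (temperature kinetics, absorbed radiation, the soil
water trajectory, the phenology masks) are precomputed once per cell in
``CellForcing`` so a single likelihood evaluation costs one pass of scalar
arithmetic over the growing window.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_season(
    tmean,
    par,
    conv,
    swr,
    fv,
    fj,
    kmm,
    gs,
    grow,
    leaf,
    ci,
    k_ext,
    sla,
    vcmax25,
    jmax25,
    theta,
    phi,
    rd_frac,
    growth_eff,
    leaf_partition,
    co2_sens,
    drought_sens,
    cold_threshold,
    cold_sens,
    b_above0,
    b_leaf0,
    traj_above,
    traj_leaf,
):
    """One growing season; returns (final aboveground biomass, max LAI).

    ``traj_above``/``traj_leaf`` receive end-of-day biomass (g m-2).
    """
    b_above = b_above0
    b_leaf = b_leaf0
    lai_max = sla * b_leaf
    n = tmean.shape[0]
    for d in range(n):
        if grow[d]:
            light = par[d]
            if light > 0.0:
                vc = co2_sens * vcmax25 * fv[d]
                ac = vc * (ci - gs[d]) / (ci + kmm[d])
                jm = co2_sens * jmax25 * fj[d]
                bb = phi * light + jm
                disc = bb * bb - 4.0 * theta * phi * light * jm
                if disc < 0.0:
                    disc = 0.0
                j = (bb - np.sqrt(disc)) / (2.0 * theta)
                aj = j * (ci - gs[d]) / (4.0 * ci + 8.0 * gs[d])
                a = ac if ac < aj else aj
                a = a - rd_frac * vc
                if a < 0.0:
                    a = 0.0
                fabs = 1.0 - np.exp(-k_ext * sla * b_leaf)
                ds = swr[d] ** drought_sens
                cold_def = cold_threshold - tmean[d]
                if cold_def > 0.0:
                    cs = 1.0 - cold_sens * cold_def
                else:
                    cs = 1.0
                if cs < 0.0:
                    cs = 0.0
                gain = a * fabs * ds * cs * conv[d] * growth_eff
                b_above += gain
                if leaf[d]:
                    b_leaf += leaf_partition * gain
                la = sla * b_leaf
                if la > lai_max:
                    lai_max = la
        traj_above[d] = b_above
        traj_leaf[d] = b_leaf
    return b_above, lai_max


@njit(cache=True)
def run_years(
    tmean2,
    par2,
    conv2,
    swr2,
    fv2,
    fj2,
    kmm2,
    gs2,
    grow2,
    leaf2,
    ndays,
    ci_by_year,
    k_ext,
    sla,
    vcmax25,
    jmax25,
    theta,
    phi,
    rd_frac,
    growth_eff,
    leaf_partition,
    co2_sens,
    drought_sens,
    cold_threshold,
    cold_sens,
    b_above0,
    b_leaf0,
    out_biomass,
    out_laimax,
):
    """Vectorized multi-year driver over padded per-season arrays."""
    n_years = ndays.shape[0]
    for y in range(n_years):
        n = ndays[y]
        ta = np.empty(n)
        tl = np.empty(n)
        b, lm = run_season(
            tmean2[y, :n],
            par2[y, :n],
            conv2[y, :n],
            swr2[y, :n],
            fv2[y, :n],
            fj2[y, :n],
            kmm2[y, :n],
            gs2[y, :n],
            grow2[y, :n],
            leaf2[y, :n],
            ci_by_year[y],
            k_ext,
            sla,
            vcmax25,
            jmax25,
            theta,
            phi,
            rd_frac,
            growth_eff,
            leaf_partition,
            co2_sens,
            drought_sens,
            cold_threshold,
            cold_sens,
            b_above0,
            b_leaf0,
            ta,
            tl,
        )
        out_biomass[y] = b
        out_laimax[y] = lm
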