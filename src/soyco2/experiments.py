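"""End-to-end validation experiments on synthetic studies.

The generator knows its ground truth, so the full pipeline (simulate ->
calibrate -> counterfactual) can be scored: credible-interval coverage of
the true parameters, posterior-predictive skill against the generated
yields, and recovery of the generator's true CO2 fertilization effect.
These harnesses are what the test suite and the reproduction script run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    CalibSettings,
    calibrate_cell,
    default_cell_priors,
    predictive_stats,
)
from .counterfactual import co2_effect_cell
from .crop_model import CellForcing, PhysioConstants, simulate_years
from .analysis_stats import growing_season_p_pet
from .synthetic import SynthConfig, default_cell_specs, generate_study

__all__ = ["CellRecovery", "run_recovery_study", "true_co2_effect"]


@dataclass
class CellRecovery:
    """Scores for one synthetic cell after calibration."""

    cell_id: str
    country: str
    n_covered: int  # of the 7 true parameters inside their 95% CI
    corr: float  # posterior-predictive correlation with the data
    rmse: float  # t/ha
    true_effect_t_ha: float
    est_effect_t_ha: float
    est_effect_pct: float
    posterior_sd_t_ha: float
    p_pet: float
    lai_max: float
    srad_mean: float

    @property
    def rel_error(self) -> float:
        return abs(self.est_effect_t_ha - self.true_effect_t_ha) / abs(
            self.true_effect_t_ha
        )


def true_co2_effect(
    rec, truth, pc: PhysioConstants, co2: dict, co2_fixed: float, window: tuple
) -> float:
    """Generator-truth CO2 effect (t/ha) from a paired simulation."""
    forcing = CellForcing.build(rec.weather, rec.lat, rec.hemisphere, rec.years, pc)
    idx = (forcing.years >= window[0]) & (forcing.years <= window[1])
    y_hist = simulate_years(forcing, co2, truth).yields[idx]
    y_fix = simulate_years(forcing, float(co2_fixed), truth).yields[idx]
    return float(np.mean(y_hist - y_fix))


def run_recovery_study(
    n_cells: int = 20,
    seed: int = 0,
    settings: Optional[CalibSettings] = None,
    cfg: Optional[SynthConfig] = None,
    pc: Optional[PhysioConstants] = None,
    co2_fixed: float = 339.0,
    window: tuple = (2002, 2006),
    max_draws: int = 100,
) -> list[CellRecovery]:
    """Generate, calibrate and score ``n_cells`` synthetic cells.

    The cells rotate through the three countries; the reduced default MCMC
    budget (5000 DREAM generations, 5 chains) keeps a 20-cell study within
    minutes on one CPU.
    """
    settings = settings or CalibSettings(n_steps=5_000, n_chains=5, seed=seed)
    per_country = int(np.ceil(n_cells / 3))
    cfg = cfg or SynthConfig(n_cells_per_country=per_country, seed=seed)
    pc = pc or PhysioConstants()
    specs = default_cell_specs(cfg)[:n_cells]
    study = generate_study(cfg, pc, specs=specs, with_face=False)
    priors = default_cell_priors()
    results = []
    for i, rec in enumerate(study.cells):
        truth = study.truths[rec.cell_id]
        cell_settings = CalibSettings(
            n_steps=settings.n_steps,
            n_chains=settings.n_chains,
            seed=(settings.seed + 1) * 1000 + i,
            burn_in=settings.burn_in,
        )
        post = calibrate_cell(rec, pc, priors, study.co2, cell_settings)
        ci = post.credible_interval(0.95)
        ta = truth.to_array()
        covered = int(np.sum((ci[:7, 0] <= ta) & (ta <= ci[:7, 1])))
        corr, rmse = predictive_stats(rec, post, pc, study.co2, max_draws)
        est = co2_effect_cell(
            rec, post, pc, study.co2, co2_fixed, window, max_draws=max_draws
        )
        true_eff = true_co2_effect(rec, truth, pc, study.co2, co2_fixed, window)
        forcing = CellForcing.build(rec.weather, rec.lat, rec.hemisphere, rec.years, pc)
        sim_true = simulate_years(forcing, study.co2, truth)
        p_pet = growing_season_p_pet(
            rec.weather, rec.lat, pc.planting_doy(rec.hemisphere)
        )
        # growing-season mean shortwave radiation
        srad_vals = []
        w = rec.weather
        pdoy = pc.planting_doy(rec.hemisphere)
        starts = np.nonzero(w["doy"].to_numpy() == pdoy)[0]
        srad_arr = w["srad"].to_numpy(float)
        for i0 in starts:
            if i0 + 150 <= len(w):
                srad_vals.append(float(srad_arr[i0 : i0 + 150].mean()))
        results.append(
            CellRecovery(
                cell_id=rec.cell_id,
                country=rec.country,
                n_covered=covered,
                corr=corr,
                rmse=rmse,
                true_effect_t_ha=true_eff,
                est_effect_t_ha=est.effect_t_ha,
                est_effect_pct=est.effect_pct,
                posterior_sd_t_ha=est.posterior_sd_t_ha,
                p_pet=p_pet,
                lai_max=float(np.mean(sim_true.lai_max)),
                srad_mean=float(np.mean(srad_vals)),
            )
        )
    return results
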