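"""Two-stage Bayesian calibration of the crop model.

Stage one fits leaf/canopy physiology (Vcmax25, Jmax25, SLA, growth
efficiency) to FACE-style aboveground and leaf biomass trajectories at
ambient and elevated CO2 with a simulated-tempering Metropolis sampler.
Stage two updates the seven per-cell parameters (plus a nuisance error SD)
against the cell's historical yield series with the DREAM multi-chain
sampler, independently for every grid cell.  Yield errors are independent
Gaussians across years (a diagonal multivariate normal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .crop_model import (
    PARAM_NAMES,
    CalibParams,
    CellForcing,
    PhysioConstants,
    simulate_trajectory,
    simulate_years,
)
from .data_io import CellRecord, cell_filter

__all__ = [
    "Prior",
    "PriorSpec",
    "PosteriorSample",
    "FaceObservation",
    "CalibSettings",
    "default_cell_priors",
    "default_face_priors",
    "log_likelihood_yield",
    "metropolis_tempering",
    "dream_update",
    "gelman_rubin",
    "calibrate_cell",
    "calibrate_face",
    "apply_face_posterior",
    "posterior_predict",
    "predictive_stats",
]

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Priors


@dataclass
class Prior:
    """One marginal prior.

    kinds: ``uniform(lo, hi)``, ``lognormal(mu, sigma)`` of the log,
    ``truncnorm(mu, sigma, lo, hi)``, ``loguniform(lo, hi)`` (Jeffreys-like
    1/x density, used for the error SD).
    """

    name: str
    kind: str
    a: float
    b: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "lognormal", "truncnorm", "loguniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "uniform":
            self.lo, self.hi = self.a, self.b
        elif self.kind == "lognormal":
            self.lo, self.hi = 0.0, np.inf
        elif self.kind == "loguniform":
            self.lo, self.hi = self.a, self.b
            if self.lo <= 0:
                raise ValueError("loguniform needs a positive lower bound")
        if self.lo >= self.hi:
            raise ValueError(f"empty support for prior {self.name}")

    def log_pdf(self, x: float) -> float:
        if not self.lo <= x <= self.hi:
            return -np.inf
        if self.kind == "uniform":
            return -math.log(self.hi - self.lo)
        if self.kind == "lognormal":
            if x <= 0:
                return -np.inf
            z = (math.log(x) - self.a) / self.b
            return -math.log(x * self.b) - LOG_SQRT_2PI - 0.5 * z * z
        if self.kind == "loguniform":
            return -math.log(x) - math.log(math.log(self.hi / self.lo))
        # truncnorm
        from scipy.stats import norm

        z = (x - self.a) / self.b
        lognorm = -math.log(self.b) - LOG_SQRT_2PI - 0.5 * z * z
        zlo = (self.lo - self.a) / self.b
        zhi = (self.hi - self.a) / self.b
        return lognorm - math.log(norm.cdf(zhi) - norm.cdf(zlo))

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        if self.kind == "lognormal":
            return float(rng.lognormal(self.a, self.b))
        if self.kind == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        while True:  # truncnorm by rejection (bounds are mild here)
            x = float(rng.normal(self.a, self.b))
            if self.lo <= x <= self.hi:
                return x

    def std(self) -> float:
        """Rough scale, used only to size random-walk proposals."""
        if self.kind == "uniform":
            return (self.hi - self.lo) / math.sqrt(12.0)
        if self.kind == "lognormal":
            s2 = self.b**2
            return math.sqrt((math.exp(s2) - 1.0)) * math.exp(self.a + s2 / 2.0)
        if self.kind == "loguniform":
            return (self.hi - self.lo) / math.sqrt(12.0)
        return self.b


class PriorSpec:
    """An ordered collection of marginal priors defining the parameter space."""

    def __init__(self, priors: Sequence[Prior]):
        if not priors:
            raise ValueError("need at least one prior")
        self.priors = list(priors)
        self.names = [p.name for p in self.priors]
        self._lo = np.array([p.lo for p in self.priors])
        self._hi = np.array([p.hi for p in self.priors])

    @property
    def n_dim(self) -> int:
        return len(self.priors)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.sample(rng) for p in self.priors])

    def log_pdf(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        if not self.in_support(theta):
            return -np.inf
        return float(sum(p.log_pdf(x) for p, x in zip(self.priors, theta)))

    def in_support(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self._lo) and np.all(theta <= self._hi))

    def std(self) -> np.ndarray:
        return np.array([p.std() for p in self.priors])


def default_cell_priors(include_sigma: bool = True) -> PriorSpec:
    """Realistic-bounds priors for the seven per-cell parameters (+ error SD)."""
    priors = [
        Prior("co2_sens", "lognormal", 0.0, 0.25),
        Prior("tech_intercept", "uniform", -2.0, 2.0),
        Prior("tech_slope", "truncnorm", 0.02, 0.02, -0.05, 0.1),
        Prior("drought_sens", "uniform", 0.0, 3.0),
        Prior("cold_threshold", "uniform", 0.0, 15.0),
        Prior("cold_sens", "uniform", 0.0, 0.5),
        Prior("yield_scale", "uniform", 0.1, 0.6),
    ]
    if include_sigma:
        priors.append(Prior("sigma", "loguniform", 0.01, 2.0))
    return PriorSpec(priors)


def default_face_priors() -> PriorSpec:
    """Priors for the physiology dimensions fitted against FACE biomass."""
    return PriorSpec(
        [
            Prior("vcmax25", "uniform", 50.0, 150.0),
            Prior("jmax25", "uniform", 90.0, 270.0),
            Prior("sla", "uniform", 0.01, 0.04),
            Prior("growth_eff", "uniform", 0.5, 0.9),
        ]
    )


# ---------------------------------------------------------------------------
# Likelihood


def log_likelihood_yield(
    obs: Mapping[int, float], sim: Mapping[int, float], sigma: float
) -> float:
    """Diagonal-covariance Gaussian log likelihood of observed yields.

    Years present in ``obs`` must all be simulated; independence across years
    follows from the zero off-diagonal error covariance.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ll = 0.0
    for year, y_obs in obs.items():
        if year not in sim:
            raise ValueError(f"simulated series lacks observed year {year}")
        z = (float(y_obs) - float(sim[year])) / sigma
        ll += -math.log(sigma) - LOG_SQRT_2PI - 0.5 * z * z
    return ll


def _gaussian_ll(resid: np.ndarray, sigma: float) -> float:
    n = resid.size
    return float(
        -n * (math.log(sigma) + LOG_SQRT_2PI) - 0.5 * np.dot(resid, resid) / sigma**2
    )


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorSample:
    """Retained MCMC draws with their log-posterior values."""

    draws: np.ndarray  # (n_retained, n_params)
    log_post: np.ndarray
    chain_id: np.ndarray
    acceptance_rate: float
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[0] == 0:
            raise ValueError("draws must be a non-empty (n, d) matrix")

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(d, 2) equal-tailed interval bounds."""
        a = 100.0 * (1.0 - level) / 2.0
        return np.percentile(self.draws, [a, 100.0 - a], axis=0).T

    def thin(self, max_draws: int) -> np.ndarray:
        """Evenly spaced subsample of draws (deterministic)."""
        n = self.n_retained
        if n <= max_draws:
            return self.draws
        idx = np.linspace(0, n - 1, max_draws).astype(int)
        return self.draws[idx]

    def to_csv(self, path) -> None:
        """Write the retained draws with a parameter-naming header."""
        import pandas as pd

        names = self.names or [f"p{i}" for i in range(self.draws.shape[1])]
        frame = pd.DataFrame(self.draws, columns=names)
        frame["log_post"] = self.log_post
        frame["chain_id"] = self.chain_id
        frame.to_csv(path, index=False)


@dataclass
class FaceObservation:
    """One FACE sampling date under one CO2 treatment."""

    day: int  # days after planting, >= 1
    co2_treatment: float  # ppm
    aboveground_biomass: float  # g m-2
    leaf_biomass: float  # g m-2
    sd: float  # observation SD, g m-2

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("day must be >= 1 (days after planting)")
        if self.aboveground_biomass < 0 or self.leaf_biomass < 0:
            raise ValueError("biomass must be non-negative")
        if self.leaf_biomass > self.aboveground_biomass + 1e-9:
            raise ValueError("leaf biomass cannot exceed aboveground biomass")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


# ---------------------------------------------------------------------------
# Simulated-tempering Metropolis


def _init_from_prior(
    log_post: Callable, priors: PriorSpec, rng: np.random.Generator, retries: int = 100
) -> tuple[np.ndarray, float]:
    for _ in range(retries):
        theta = priors.sample(rng)
        lp = float(log_post(theta))
        if np.isfinite(lp):
            return theta, lp
    raise RuntimeError("could not find a finite log-posterior starting point")


def metropolis_tempering(
    log_post: Callable,
    priors: PriorSpec,
    n_steps: int = 200_000,
    n_temps: int = 20,
    seed: Optional[int] = None,
    t_max: float = 50.0,
    ladder_move_prob: float = 0.1,
    burn_in: float = 0.5,
    target_accept: float = 0.3,
    occupancy_decay: float = 0.8,
    step_scale=None,
    adapt_step: bool = True,
) -> PosteriorSample:
    """Single-chain Metropolis with simulated tempering.

    The chain moves on the product space (theta, k) with stationary density
    proportional to ``exp(log_post(theta) / T_k - zeta_k)`` over a geometric
    temperature ladder ``T_1 = 1 < ... < T_{n_temps} = t_max``.  The
    pseudo-prior weights ``zeta_k`` are estimated during burn-in by a
    stepping-stone identity (the log ratio of adjacent normalizing constants
    is ``log E_k[exp((1/T_{k+1}-1/T_k) lp)]``), then frozen with a geometric
    tilt (occupancy ~ occupancy_decay**k) favouring the cold end, so more
    unit-temperature draws are retained; the conditional law of theta given
    T = 1 is the exact posterior either way.  Only unit-temperature draws
    after burn-in are retained.  ``log_post`` must be the complete
    unnormalized log target; ``priors`` provide initialization, support and
    proposal scales.
    """
    if n_steps < 1 or n_temps < 1:
        raise ValueError("n_steps and n_temps must be >= 1")
    rng = np.random.default_rng(seed)
    d = priors.n_dim
    temps = np.geomspace(1.0, t_max, n_temps) if n_temps > 1 else np.array([1.0])
    inv_t = 1.0 / temps

    theta, lp = _init_from_prior(log_post, priors, rng)
    k = 0
    if step_scale is None:
        base_scale = priors.std() * 2.4 / math.sqrt(d)
    else:
        base_scale = np.broadcast_to(np.asarray(step_scale, dtype=float), (d,)).copy()
    level_mult = np.ones(n_temps)
    zeta = np.zeros(n_temps)
    n_burn = int(burn_in * n_steps)
    n_prop = np.zeros(n_temps)
    # Running log-mean-exp accumulators for the stepping-stone ratios.
    ss_hi = np.full(n_temps, -np.inf)
    ss_acc = np.zeros(n_temps)
    ss_n = np.zeros(n_temps)
    # Temper relative to the best log-posterior seen, so ladder moves are
    # driven by the O(dim) fluctuations of lp rather than its absolute size.
    lp_ref = lp

    draws, lps = [], []
    n_acc = 0
    n_theta_moves = 0
    tilt = np.arange(n_temps) * math.log(1.0 / occupancy_decay)
    if n_burn == 0:
        zeta = zeta + tilt
    for step in range(n_steps):
        if step == n_burn and n_burn > 0:
            zeta = zeta + tilt  # freeze adaptation, favour the cold end
        if n_temps > 1 and rng.random() < ladder_move_prob:
            k_new = k + (1 if rng.random() < 0.5 else -1)
            if 0 <= k_new < n_temps:
                log_r = (inv_t[k_new] - inv_t[k]) * (lp - lp_ref) + (
                    zeta[k] - zeta[k_new]
                )
                if math.log(rng.random()) < log_r:
                    k = k_new
        else:
            n_theta_moves += 1
            n_prop[k] += 1
            scale = base_scale * level_mult[k] * math.sqrt(temps[k])
            prop = theta + scale * rng.standard_normal(d)
            accepted = False
            if priors.in_support(prop):
                lp_prop = float(log_post(prop))
                if math.log(rng.random()) < (lp_prop - lp) * inv_t[k]:
                    theta, lp = prop, lp_prop
                    accepted = True
                    n_acc += 1
            if adapt_step and step < n_burn:
                eta = min(0.1, 10.0 / (10.0 + n_prop[k]))
                level_mult[k] *= math.exp(eta * ((1.0 if accepted else 0.0) - target_accept))

        if step < n_burn and n_temps > 1:
            if lp > lp_ref + 5.0:
                # A much better mode was found: re-anchor and restart the
                # ratio estimates, which were relative to the old anchor.
                lp_ref = lp
                ss_hi[:] = -np.inf
                ss_acc[:] = 0.0
                ss_n[:] = 0.0
            if k < n_temps - 1:
                val = (inv_t[k + 1] - inv_t[k]) * (lp - lp_ref)
                if val > ss_hi[k]:
                    ss_acc[k] = ss_acc[k] * math.exp(ss_hi[k] - val) + 1.0
                    ss_hi[k] = val
                else:
                    ss_acc[k] += math.exp(val - ss_hi[k])
                ss_n[k] += 1.0
            if step % 100 == 99:
                log_r = np.where(
                    ss_n[:-1] > 0,
                    ss_hi[:-1] + np.log(np.maximum(ss_acc[:-1], 1e-300))
                    - np.log(np.maximum(ss_n[:-1], 1.0)),
                    0.0,
                )
                zeta[1:] = np.cumsum(log_r)

        if step >= n_burn and k == 0:
            draws.append(theta.copy())
            lps.append(lp)

    if not draws:
        raise RuntimeError(
            "no unit-temperature draws retained; increase n_steps or reduce t_max"
        )
    return PosteriorSample(
        draws=np.asarray(draws),
        log_post=np.asarray(lps),
        chain_id=np.zeros(len(draws), dtype=np.int64),
        acceptance_rate=n_acc / max(n_theta_moves, 1),
        names=list(priors.names),
    )


# ---------------------------------------------------------------------------
# DREAM


def dream_update(
    log_post: Callable,
    priors: PriorSpec,
    n_steps: int = 50_000,
    n_chains: int = 10,
    seed: Optional[int] = None,
    burn_in: float = 0.5,
    n_cr: int = 3,
    p_unit_gamma: float = 0.2,
    jitter: float = 0.05,
    eps_scale: float = 1e-6,
    outlier_check: bool = True,
) -> PosteriorSample:
    """DiffeRential Evolution Adaptive Metropolis sampler.

    Each chain proposes jumps built from the difference of two other randomly
    chosen chains, restricted to a random per-dimension crossover subspace;
    the crossover probabilities adapt during burn-in from normalized jump
    distances, and with probability ``p_unit_gamma`` the jump rate is set to
    one to enable mode swaps.  Outlier chains (aberrantly low mean
    log-posterior) are reset to the best chain during burn-in only.  Retains
    all post-burn-in states of all chains.
    """
    if n_chains < 4:
        raise ValueError("DREAM needs at least 4 chains")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    d = priors.n_dim

    states = np.empty((n_chains, d))
    lp = np.empty(n_chains)
    for c in range(n_chains):
        states[c], lp[c] = _init_from_prior(log_post, priors, rng)

    cr_vals = (np.arange(n_cr) + 1.0) / n_cr
    p_cr = np.full(n_cr, 1.0 / n_cr)
    j_dist = np.zeros(n_cr)
    n_cr_used = np.zeros(n_cr)

    n_burn = int(burn_in * n_steps)
    check_every = max(10, n_steps // 20)
    lp_history: list[np.ndarray] = []

    draws, lps, cids = [], [], []
    n_acc = 0
    n_prop_total = 0
    for step in range(n_steps):
        std = states.std(axis=0)
        std[std == 0] = 1.0
        for c in range(n_chains):
            others = rng.choice(n_chains - 1, size=2, replace=False)
            others = np.where(others >= c, others + 1, others)
            r1, r2 = int(others[0]), int(others[1])

            m = int(rng.choice(n_cr, p=p_cr))
            sel = rng.random(d) < cr_vals[m]
            if not sel.any():
                sel[int(rng.integers(d))] = True
            d_eff = int(sel.sum())
            gamma = 1.0 if rng.random() < p_unit_gamma else 2.38 / math.sqrt(2.0 * d_eff)
            e = rng.uniform(-jitter, jitter, size=d_eff)
            prop = states[c].copy()
            prop[sel] = (
                states[c, sel]
                + (1.0 + e) * gamma * (states[r1, sel] - states[r2, sel])
                + eps_scale * rng.standard_normal(d_eff)
            )
            n_prop_total += 1
            n_cr_used[m] += 1
            if priors.in_support(prop):
                lp_prop = float(log_post(prop))
                if math.log(rng.random()) < lp_prop - lp[c]:
                    jump = (prop - states[c]) / std
                    j_dist[m] += float(np.dot(jump, jump))
                    states[c] = prop
                    lp[c] = lp_prop
                    n_acc += 1

        if step < n_burn:
            # Adapt crossover selection probabilities from jump distances.
            if step > 0 and step % 10 == 0 and j_dist.sum() > 0:
                w = j_dist / np.maximum(n_cr_used, 1.0)
                if w.sum() > 0:
                    p_cr = 0.9 * p_cr + 0.1 * (w / w.sum())
                    p_cr /= p_cr.sum()
            lp_history.append(lp.copy())
            if outlier_check and step > 0 and step % check_every == 0:
                hist = np.asarray(lp_history[len(lp_history) // 2 :])
                mean_lp = hist.mean(axis=0)
                q1, q3 = np.percentile(mean_lp, [25, 75])
                cutoff = q1 - 2.0 * (q3 - q1)
                best = int(np.argmax(lp))
                for c in np.nonzero(mean_lp < cutoff)[0]:
                    states[c] = states[best].copy()
                    lp[c] = lp[best]
        else:
            draws.append(states.copy())
            lps.append(lp.copy())
            cids.append(np.arange(n_chains))

    if not draws:
        raise RuntimeError("no post-burn-in draws retained; increase n_steps")
    return PosteriorSample(
        draws=np.concatenate(draws, axis=0),
        log_post=np.concatenate(lps),
        chain_id=np.concatenate(cids),
        acceptance_rate=n_acc / max(n_prop_total, 1),
        names=list(priors.names),
    )


def gelman_rubin(sample: PosteriorSample) -> np.ndarray:
    """Potential scale reduction factor per dimension from the chain labels."""
    chain_ids = np.unique(sample.chain_id)
    if chain_ids.size < 2:
        raise ValueError("need at least two chains for the diagnostic")
    chains = [sample.draws[sample.chain_id == c] for c in chain_ids]
    n = min(len(c) for c in chains)
    x = np.stack([c[-n:] for c in chains])  # (m, n, d)
    m = x.shape[0]
    means = x.mean(axis=1)  # (m, d)
    b = n * means.var(axis=0, ddof=1)
    w = x.var(axis=1, ddof=1).mean(axis=0)
    var_hat = (n - 1) / n * w + b / n
    return np.sqrt(var_hat / np.where(w > 0, w, 1.0))


# ---------------------------------------------------------------------------
# Cell and FACE calibration drivers


@dataclass
class CalibSettings:
    """MCMC budgets; full-scale study values by default."""

    n_steps: int = 50_000
    n_chains: int = 10
    seed: int = 0
    burn_in: float = 0.5
    # FACE stage
    face_n_steps: int = 200_000
    face_n_temps: int = 20


def _cell_log_post_factory(
    forcing: CellForcing,
    obs_years: np.ndarray,
    obs_yields: np.ndarray,
    priors: PriorSpec,
    co2: Mapping[int, float],
):
    year_index = np.searchsorted(forcing.years, obs_years)

    def log_post(theta: np.ndarray) -> float:
        lp = priors.log_pdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        cp = CalibParams.from_array(theta[:7])
        sigma = float(theta[7])
        sim = simulate_years(forcing, co2, cp)
        resid = obs_yields - sim.yields[year_index]
        return lp + _gaussian_ll(resid, sigma)

    return log_post


def calibrate_cell(
    rec: CellRecord,
    pc: PhysioConstants,
    priors: Optional[PriorSpec],
    co2: Mapping[int, float],
    settings: Optional[CalibSettings] = None,
) -> PosteriorSample:
    """Per-cell DREAM update of the seven parameters plus the error SD."""
    if not cell_filter(rec):
        raise ValueError(f"cell {rec.cell_id} does not pass the eligibility filter")
    if rec.weather is None:
        raise ValueError(f"cell {rec.cell_id} has no weather attached")
    priors = priors or default_cell_priors()
    settings = settings or CalibSettings()
    obs_years = rec.years
    obs_yields = np.array([rec.yields[int(y)] for y in obs_years])
    forcing = CellForcing.build(rec.weather, rec.lat, rec.hemisphere, obs_years, pc)
    log_post = _cell_log_post_factory(forcing, obs_years, obs_yields, priors, co2)
    return dream_update(
        log_post,
        priors,
        n_steps=settings.n_steps,
        n_chains=settings.n_chains,
        seed=settings.seed,
        burn_in=settings.burn_in,
    )


def calibrate_face(
    face_obs: Sequence[FaceObservation],
    weather,
    lat: float,
    pc: PhysioConstants,
    priors: Optional[PriorSpec] = None,
    settings: Optional[CalibSettings] = None,
    hemisphere: str = "north",
) -> PosteriorSample:
    """Fit physiology to FACE biomass trajectories by simulated tempering.

    ``weather`` is a single-season weather table covering the planting window;
    treatments are grouped by their CO2 level and compared against simulated
    trajectories with independent Gaussian errors at each observation's SD.
    """
    if not face_obs:
        raise ValueError("need at least one FACE observation")
    priors = priors or default_face_priors()
    settings = settings or CalibSettings()
    years = [int(weather["year"].min()) if hemisphere == "north" else int(weather["year"].max())]
    forcing = CellForcing.build(weather, lat, hemisphere, years, pc)
    cp = CalibParams()  # stress-free, trend-free growth
    max_day = int(forcing.ndays[0])
    for o in face_obs:
        if o.day > max_day:
            raise ValueError(f"observation day {o.day} beyond the simulated window")
    treatments = sorted({o.co2_treatment for o in face_obs})
    by_treatment = {
        ca: [o for o in face_obs if o.co2_treatment == ca] for ca in treatments
    }

    def log_post(theta: np.ndarray) -> float:
        lp = priors.log_pdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        vcmax25, jmax25, sla, geff = (float(t) for t in theta)
        for ca, obs in by_treatment.items():
            ta, tl = simulate_trajectory(
                forcing, 0, ca, cp,
                vcmax25=vcmax25, jmax25=jmax25, sla=sla, growth_eff=geff,
            )
            for o in obs:
                za = (o.aboveground_biomass - ta[o.day - 1]) / o.sd
                zl = (o.leaf_biomass - tl[o.day - 1]) / o.sd
                lp += -2.0 * (math.log(o.sd) + LOG_SQRT_2PI) - 0.5 * (za * za + zl * zl)
        return lp

    return metropolis_tempering(
        log_post,
        priors,
        n_steps=settings.face_n_steps,
        n_temps=settings.face_n_temps,
        seed=settings.seed,
        burn_in=settings.burn_in,
    )


def apply_face_posterior(pc: PhysioConstants, post: PosteriorSample) -> PhysioConstants:
    """Freeze the FACE-stage posterior means into the physiological constants."""
    means = dict(zip(post.names, post.mean()))
    return pc.replace(
        vcmax25=means["vcmax25"],
        jmax25=means["jmax25"],
        sla=means["sla"],
        growth_eff=means["growth_eff"],
    )


def posterior_predict(
    forcing: CellForcing,
    post: PosteriorSample,
    co2: Mapping[int, float],
    max_draws: int = 100,
) -> np.ndarray:
    """Posterior-mean simulated yield per forcing year."""
    draws = post.thin(max_draws)
    acc = np.zeros(len(forcing.years))
    for theta in draws:
        acc += simulate_years(forcing, co2, CalibParams.from_array(theta[:7])).yields
    return acc / len(draws)


def predictive_stats(
    rec: CellRecord,
    post: PosteriorSample,
    pc: PhysioConstants,
    co2: Mapping[int, float],
    max_draws: int = 100,
) -> tuple[float, float]:
    """(Pearson correlation, RMSE in t/ha) of posterior-mean prediction."""
    obs_years = rec.years
    obs = np.array([rec.yields[int(y)] for y in obs_years])
    forcing = CellForcing.build(rec.weather, rec.lat, rec.hemisphere, obs_years, pc)
    pred = posterior_predict(forcing, post, co2, max_draws)
    corr = float(np.corrcoef(obs, pred)[0, 1])
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return corr, rmse
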