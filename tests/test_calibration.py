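"""Likelihood, priors, and the two MCMC samplers on analytic targets."""

import numpy as np
import pytest
from scipy import stats

from soyco2.calibration import (
    CalibSettings,
    Prior,
    PriorSpec,
    calibrate_cell,
    calibrate_face,
    apply_face_posterior,
    default_cell_priors,
    default_face_priors,
    dream_update,
    gelman_rubin,
    log_likelihood_yield,
    metropolis_tempering,
)
from soyco2.synthetic import SynthConfig, gen_face, generate_study


LOG_INV_SQRT_2PI = -0.5 * np.log(2 * np.pi)


class TestPriors:
    def test_support_and_logpdf(self):
        spec = default_cell_priors()
        assert spec.n_dim == 8
        rng = np.random.default_rng(0)
        for _ in range(200):
            theta = spec.sample(rng)
            assert spec.in_support(theta)
            assert np.isfinite(spec.log_pdf(theta))
        outside = spec.sample(rng)
        outside[6] = 0.05  # below the yield_scale lower bound
        assert spec.log_pdf(outside) == -np.inf

    def test_lognormal_density_matches_scipy(self):
        p = Prior("x", "lognormal", 0.1, 0.3)
        for x in (0.5, 1.0, 2.0):
            assert p.log_pdf(x) == pytest.approx(
                stats.lognorm.logpdf(x, s=0.3, scale=np.exp(0.1)), abs=1e-12
            )

    def test_truncnorm_density_matches_scipy(self):
        p = Prior("x", "truncnorm", 0.02, 0.02, -0.05, 0.1)
        a, b = (-0.05 - 0.02) / 0.02, (0.1 - 0.02) / 0.02
        for x in (-0.01, 0.02, 0.08):
            assert p.log_pdf(x) == pytest.approx(
                stats.truncnorm.logpdf(x, a, b, loc=0.02, scale=0.02), abs=1e-10
            )


class TestYieldLikelihood:
    def test_zero_residuals(self):
        obs = {y: 2.0 for y in range(1990, 2000)}
        ll = log_likelihood_yield(obs, obs, sigma=1.0)
        assert ll == pytest.approx(10 * LOG_INV_SQRT_2PI)

    def test_unit_z_score(self):
        ll = log_likelihood_yield({2000: 2.5}, {2000: 2.0}, sigma=0.5)
        assert ll == pytest.approx(-0.5 - np.log(0.5 * np.sqrt(2 * np.pi)))

    def test_matches_dense_mvn(self, rng):
        years = list(range(1990, 2000))
        obs = {y: float(rng.uniform(1, 4)) for y in years}
        sim = {y: float(rng.uniform(1, 4)) for y in years}
        sigma = 0.31
        dense = stats.multivariate_normal.logpdf(
            [obs[y] for y in years],
            mean=[sim[y] for y in years],
            cov=np.eye(10) * sigma**2,
        )
        assert log_likelihood_yield(obs, sim, sigma) == pytest.approx(dense, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            log_likelihood_yield({2000: 1.0}, {2000: 1.0}, sigma=0.0)
        with pytest.raises(ValueError):
            log_likelihood_yield({2000: 1.0}, {1999: 1.0}, sigma=1.0)


class TestTempering:
    def test_prior_recovery_under_flat_likelihood(self):
        pri = PriorSpec([Prior("x", "uniform", -10, 10)])
        post = metropolis_tempering(pri.log_pdf, pri, n_steps=50_000, n_temps=10,
                                    seed=7)
        sd = 20 / np.sqrt(12)
        assert abs(post.draws.mean()) < 0.06 * sd
        assert post.draws.std() == pytest.approx(sd, rel=0.08)

    def test_draws_stay_in_support_and_are_reproducible(self):
        # a lognormal-shaped target on x > 0; mild ladder so the hot chain
        # stays integrable
        pri = PriorSpec([Prior("x", "lognormal", 0.0, 0.5)])
        lp = lambda th: float(-0.5 * (np.log(th[0]) / 0.4) ** 2 - np.log(th[0]))
        a = metropolis_tempering(lp, pri, n_steps=20_000, n_temps=5, seed=3,
                                 t_max=5.0)
        b = metropolis_tempering(lp, pri, n_steps=20_000, n_temps=5, seed=3,
                                 t_max=5.0)
        assert np.all(a.draws > 0)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_post, b.log_post)

    def test_rejects_bad_arguments(self):
        pri = PriorSpec([Prior("x", "uniform", 0, 1)])
        with pytest.raises(ValueError):
            metropolis_tempering(lambda t: 0.0, pri, n_steps=0, n_temps=5)
        with pytest.raises(RuntimeError, match="finite log-posterior"):
            metropolis_tempering(lambda t: -np.inf, pri, n_steps=10, n_temps=2)


class TestDream:
    def test_requires_four_chains(self):
        pri = PriorSpec([Prior("x", "uniform", -1, 1)])
        with pytest.raises(ValueError, match="4 chains"):
            dream_update(lambda t: 0.0, pri, n_steps=10, n_chains=3)

    def test_correlated_gaussian_moments_and_rhat(self):
        pri = PriorSpec([Prior("a", "uniform", -10, 10),
                         Prior("b", "uniform", -10, 10)])
        icov = np.linalg.inv(np.array([[1.0, 0.8], [0.8, 1.0]]))
        lp = lambda th: float(-0.5 * th @ icov @ th)
        post = dream_update(lp, pri, n_steps=4000, n_chains=10, seed=3)
        assert np.abs(post.draws.mean(axis=0)).max() < 0.05
        corr = np.corrcoef(post.draws.T)[0, 1]
        assert corr == pytest.approx(0.8, abs=0.05)
        assert np.all(gelman_rubin(post) < 1.2)

    def test_prior_recovery_and_support(self):
        pri = PriorSpec([Prior("a", "uniform", 2, 4),
                         Prior("b", "lognormal", 0.0, 0.25)])
        post = dream_update(pri.log_pdf, pri, n_steps=3000, n_chains=8, seed=5)
        assert np.all(post.draws[:, 0] >= 2) and np.all(post.draws[:, 0] <= 4)
        assert np.all(post.draws[:, 1] > 0)
        assert post.draws[:, 0].mean() == pytest.approx(3.0, abs=0.1)
        # lognormal(0, 0.25) mean = exp(0.25^2/2)
        assert post.draws[:, 1].mean() == pytest.approx(np.exp(0.03125), abs=0.1)

    def test_reproducible(self):
        pri = PriorSpec([Prior("x", "uniform", -5, 5)])
        lp = lambda th: float(-0.5 * th[0] ** 2)
        a = dream_update(lp, pri, n_steps=500, n_chains=5, seed=11)
        b = dream_update(lp, pri, n_steps=500, n_chains=5, seed=11)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.chain_id, b.chain_id)


@pytest.fixture(scope="module")
def study():
    return generate_study(SynthConfig(n_cells_per_country=1, seed=9),
                          with_face=False)


class TestCellCalibration:
    def test_requires_eligible_cell(self, study, pc):
        rec = study.cells[0]
        bad = type(rec)(
            cell_id=rec.cell_id, lat=rec.lat, lon=rec.lon, country=rec.country,
            yields=rec.yields, harvest_area_fraction=0.001, weather=rec.weather,
        )
        with pytest.raises(ValueError, match="eligibility"):
            calibrate_cell(bad, pc, None, study.co2)

    def test_likelihood_washout_returns_the_prior(self, study, pc):
        """With the error SD forced to be huge, the posterior is the prior."""
        rec = study.cells[0]
        priors = default_cell_priors(include_sigma=False)
        washed = PriorSpec(priors.priors + [Prior("sigma", "loguniform", 80.0, 120.0)])
        post = calibrate_cell(
            rec, pc, washed, study.co2,
            CalibSettings(n_steps=2500, n_chains=6, seed=4),
        )
        rng = np.random.default_rng(0)
        prior_draws = np.array([washed.sample(rng) for _ in range(4000)])
        for i in range(7):
            d = stats.ks_2samp(post.draws[:, i], prior_draws[:, i]).statistic
            assert d < 0.1, f"dimension {washed.names[i]}: KS distance {d:.3f}"


class TestFaceCalibration:
    def test_recovers_predictive_trajectories(self, pc):
        cfg = SynthConfig(seed=2)
        obs, weather, lat = gen_face(cfg, pc)
        post = calibrate_face(
            obs, weather, lat, pc,
            settings=CalibSettings(face_n_steps=15_000, face_n_temps=10, seed=5),
        )
        assert post.n_retained > 100
        lo = default_face_priors()
        assert np.all(post.draws >= lo._lo) and np.all(post.draws <= lo._hi)
        pc_cal = apply_face_posterior(pc, post)
        # the fitted physiology should reproduce observed final biomass within
        # a few observation SDs
        from soyco2.crop_model import CellForcing, CalibParams, simulate_trajectory

        forcing = CellForcing.build(weather, lat, "north", [2000], pc_cal)
        last = max(o.day for o in obs)
        for ca in (372.0, 552.0):
            ta, _ = simulate_trajectory(forcing, 0, ca, CalibParams())
            ob = [o for o in obs if o.co2_treatment == ca and o.day == last][0]
            assert abs(ta[last - 1] - ob.aboveground_biomass) < 5 * ob.sd
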