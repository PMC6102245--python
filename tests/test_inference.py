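import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import harvestssm as h
from harvestssm.inference import (
    AgeAtHarvestModel,
    MCMCConfig,
    adaptive_block_metropolis,
    desk_config,
    gelman_rubin,
    posterior_summary,
    run_mcmc,
)
from harvestssm.observation import joint_loglik


class TestConfig:
    def test_defaults_follow_production_run(self):
        cfg = MCMCConfig()
        assert (cfg.n_iterations, cfg.n_chains, cfg.burn_in, cfg.thin) == (
            220_000, 3, 20_000, 4)
        assert cfg.rhat_threshold == 1.1

    def test_retained_formula(self):
        cfg = MCMCConfig(n_iterations=1000, burn_in=103, thin=7)
        assert cfg.n_retained == (1000 - 103) // 7

    def test_invalid(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)


class TestLogPosterior:
    def test_equals_scipy_route(self, model, default_priors, sim_data):
        """Dual-route check: JIT core vs scipy densities + python likelihood."""
        p = default_priors
        Y = model.Y
        rng = np.random.default_rng(5)
        for _ in range(3):
            th = model.initial_theta(rng)
            lp_core = model.log_posterior(th)

            vit = model.vitals_from_theta(th)
            ll = joint_loglik(sim_data, model.abundance(th), vit)
            pr = 0.0
            for i, s in enumerate(p.LS):
                x = math.exp(th[i])
                pr += stats.gamma.logpdf(x, s.hyper_a, scale=1 / s.hyper_b) + th[i]
            for i, s in enumerate(p.PR):
                x = expit(th[4 + i])
                pr += stats.beta.logpdf(x, s.hyper_a, s.hyper_b) + math.log(x * (1 - x))
            x = expit(th[8])
            pr += stats.beta.logpdf(x, p.SP.hyper_a, p.SP.hyper_b) + math.log(x * (1 - x))
            for idx, s in ((9, p.CubSa), (10, p.CubSb), (11, p.Rep), (12, p.Rep),
                           (13, p.HSf)):
                pr += stats.norm.logpdf(th[idx], s.link_mean, s.link_sd)
            pr += stats.norm.logpdf(th[13] + th[14], p.HSm.link_mean, p.HSm.link_sd)
            pr += stats.norm.logpdf(th[16 + Y], p.NS.link_mean, p.NS.link_sd)
            shape, rate = p.HSf.annual_precision_prior
            tau = math.exp(th[15 + Y])
            pr += stats.gamma.logpdf(tau, shape, scale=1 / rate) + th[15 + Y]
            pr += stats.norm.logpdf(th[15:15 + Y], th[13], 1 / math.sqrt(tau)).sum()
            tau2 = math.exp(th[17 + 2 * Y])
            pr += stats.gamma.logpdf(tau2, shape, scale=1 / rate) + th[17 + 2 * Y]
            pr += stats.norm.logpdf(th[17 + Y:17 + 2 * Y], th[16 + Y],
                                    1 / math.sqrt(tau2)).sum()
            pr += stats.norm.logpdf(th[18 + 2 * Y:21 + 2 * Y], 0, p.age_offset_sd).sum()
            pr += stats.norm.logpdf(th[21 + 2 * Y],
                                    math.log(p.initial_population.n_total),
                                    p.initial_population.dispersion)
            assert lp_core == pytest.approx(ll + pr, abs=1e-7)

    def test_finite_at_prior_center(self, model):
        assert np.isfinite(model.log_posterior(model.prior_center_theta()))

    def test_off_support_is_minus_inf_not_crash(self, model):
        th = model.prior_center_theta()
        th[0] = 1e4  # absurd litter size on the log scale -> overflow territory
        assert model.log_posterior(th) == -np.inf

    def test_flat_prior_difference_is_likelihood_difference(self, sim_data,
                                                            default_priors):
        """With Beta(1,1) on a pregnancy rate, moving it changes the posterior
        by exactly the likelihood difference plus the logit Jacobian."""
        import dataclasses

        from harvestssm.priors import PriorSpec

        flat = dataclasses.replace(
            default_priors,
            PR=tuple([PriorSpec(s.name, "beta", 1.0, 1.0) for s in default_priors.PR]),
        )
        m = AgeAtHarvestModel(sim_data, flat)
        th1 = m.prior_center_theta()
        th2 = th1.copy()
        th2[5] += 0.3
        dlp = m.log_posterior(th2) - m.log_posterior(th1)
        ll1 = joint_loglik(sim_data, m.abundance(th1), m.vitals_from_theta(th1))
        ll2 = joint_loglik(sim_data, m.abundance(th2), m.vitals_from_theta(th2))
        p1, p2 = expit(th1[5]), expit(th2[5])
        jac = math.log(p2 * (1 - p2)) - math.log(p1 * (1 - p1))
        assert dlp == pytest.approx(ll2 - ll1 + jac, abs=1e-7)


class TestGelmanRubin:
    def test_identical_chains_closed_form(self):
        draws = np.tile(np.random.default_rng(0).normal(size=200), (2, 1))
        n = draws.shape[1]
        assert gelman_rubin(draws) == pytest.approx(math.sqrt((n - 1) / n))

    def test_separated_chains_diverge(self):
        rng = np.random.default_rng(1)
        draws = np.vstack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(draws) > 1.1

    def test_matches_arviz_identity_method(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 400))
        mine = gelman_rubin(draws)
        theirs = float(arviz.rhat(arviz.convert_to_dataset(draws),
                                  method="identity")["x"])
        assert mine == pytest.approx(theirs, abs=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))

    def test_well_mixed_near_one(self):
        rng = np.random.default_rng(3)
        assert gelman_rubin(rng.normal(size=(3, 2000))) == pytest.approx(1.0, abs=0.02)


class TestSamplerOracle:
    def test_conjugate_beta_binomial(self):
        """Sampler correctness oracle: posterior mean within 3 MC SEs of the
        closed-form beta posterior."""
        a0, b0, n, k = 2.0, 3.0, 40, 27

        def logpost(x):
            p = expit(x[0])
            return (stats.binom.logpmf(k, n, p) + stats.beta.logpdf(p, a0, b0)
                    + math.log(p * (1 - p)))

        rng = np.random.default_rng(99)
        chain_means = []
        for c in range(4):
            draws, _, _ = adaptive_block_metropolis(
                logpost, np.array([0.0]), [np.array([0])],
                n_iterations=5000, burn_in=1000, thin=1,
                rng=np.random.default_rng(1000 + c))
            chain_means.append(expit(draws[:, 0]).mean())
        post_mean = (a0 + k) / (a0 + b0 + n)
        est = float(np.mean(chain_means))
        mcse = float(np.std(chain_means, ddof=1) / math.sqrt(len(chain_means)))
        assert abs(est - post_mean) < 3 * max(mcse, 1e-4)

    def test_conjugate_posterior_mode_of_log_density(self):
        # closed-form MAP of the conjugate toy on the probability scale
        a0, b0, n, k = 3.0, 4.0, 20, 8
        grid = np.linspace(0.01, 0.99, 9801)
        dens = stats.binom.logpmf(k, n, grid) + stats.beta.logpdf(grid, a0, b0)
        mode = grid[np.argmax(dens)]
        assert mode == pytest.approx((a0 + k - 1) / (a0 + b0 + n - 2), abs=1e-3)


class TestRunMcmc:
    def test_determinism(self, sim_data, default_priors):
        cfg = desk_config(seed=21, n_iterations=3000, burn_in=1500)
        s1 = run_mcmc(sim_data, default_priors, cfg)
        s2 = run_mcmc(sim_data, default_priors, cfg)
        np.testing.assert_array_equal(s1.thetas, s2.thetas)

    def test_retained_counts(self, desk_fit):
        cfg = desk_fit.config
        assert desk_fit.thetas.shape[1] == (cfg.n_iterations - cfg.burn_in) // cfg.thin

    def test_desk_fit_converges(self, desk_fit):
        rhat = desk_fit.rhat()
        assert float(rhat.max()) < 1.1
        assert desk_fit.converged()

    def test_probability_draws_in_unit_interval(self, desk_fit):
        rd = desk_fit.real_draws()
        for name in ("PR_2.5", "SP_f", "CubSa", "CubSb", "Rep_F", "Rep_M",
                     "HS_F", "HS_M", "NS"):
            v = rd[name]
            assert np.all((v >= 0) & (v <= 1)), name

    def test_abundance_draws_nonnegative(self, desk_fit):
        assert np.all(desk_fit.abundance_draws() >= 0)

    def test_posterior_centers_near_truth(self, desk_fit, sim_truth):
        rd = desk_fit.real_draws()
        assert rd["Rep_F"].mean() == pytest.approx(0.98, abs=0.04)
        assert rd["NS"].mean() == pytest.approx(0.95, abs=0.04)
        totals = desk_fit.abundance_draws().mean(axis=(0, 1))
        truth_totals = sim_truth.abundance.total_by_year()
        assert np.all(np.abs(totals / truth_totals - 1) < 0.15)


class TestSummaries:
    def test_constant_draws(self):
        v = np.full(50, 7.0)
        assert v.mean() == 7.0
        assert np.percentile(v, 2.5) == np.percentile(v, 97.5) == 7.0

    def test_percentile_rule(self):
        draws = np.arange(1.0, 101.0)
        assert np.percentile(draws, 2.5) == pytest.approx(3.475)
        assert np.percentile(draws, 97.5) == pytest.approx(97.525)

    def test_totals_are_sums_per_draw(self, desk_fit):
        from harvestssm import _core

        m = desk_fit.model
        th = desk_fit.thetas[0, 0]
        N = np.asarray(_core._project(th, m.prop0, m.fecmap, m.Y, m.A))
        assert desk_fit.abundance_draws()[0, 0, 0] == pytest.approx(N[:, :, 0].sum())

    def test_summary_frame(self, desk_fit):
        summary = posterior_summary(desk_fit)
        assert "N_total_2009" in summary.index
        assert f"N_total_{2009 + desk_fit.model.Y}" in summary.index
        assert set(summary.columns) == {"mean", "sd", "cri_2.5", "cri_97.5"}
        assert (summary["cri_2.5"] <= summary["cri_97.5"]).all()

    def test_draws_long_frame(self, desk_fit):
        frame = desk_fit.to_frame()
        C, D, P = desk_fit.thetas.shape
        assert len(frame) == C * D * P
        assert set(frame.columns) == {"chain", "iteration", "parameter", "value"}

    def test_inference_data_export(self, desk_fit):
        pytest.importorskip("arviz")
        idata = desk_fit.to_inference_data()
        assert "N_total" in idata.posterior
        assert idata.posterior["Rep_F"].shape == desk_fit.thetas.shape[:2]


class TestInitializationFailure:
    def test_error_names_first_year(self, default_priors, sim_data):
        import dataclasses

        cfg = desk_config(seed=0, n_iterations=200, burn_in=100, max_init_retries=0)
        with pytest.raises(RuntimeError, match="2009"):
            run_mcmc(sim_data, default_priors, cfg)
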