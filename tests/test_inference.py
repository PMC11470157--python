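"""MCMC engine and posterior summaries: diagnostics against independent
oracles, known-target sampling, conjugate closed forms, latent-fate full
conditionals, seeded determinism, and prior-recovery runs."""

import numpy as np
import pytest
from scipy import stats

import nestfidelity as nf
from nestfidelity.fidelity import DailySurvivalPrior
from nestfidelity.inference import (
    FidelityMCMC,
    MCMCConfig,
    Model,
    ParamSpec,
    fit_fidelity,
    fit_survival,
    gelman_rubin,
    hpdi,
    run_mcmc,
    sign_probability,
)


class TestGelmanRubin:
    def test_same_distribution_near_one(self, rng):
        chains = rng.standard_normal((3, 5000))
        assert 1.0 <= gelman_rubin(chains) < 1.02

    def test_separated_chains_flagged(self, rng):
        chains = np.stack(
            [rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)]
        )
        assert gelman_rubin(chains) > 3.0

    def test_constant_chains_convention(self):
        with pytest.warns(UserWarning):
            assert gelman_rubin(np.ones((3, 100))) == 1.0

    def test_split_halves_detect_trend(self, rng):
        # a within-chain drift the unsplit statistic would miss
        drift = np.linspace(0, 5, 2000)
        chains = rng.standard_normal((2, 2000)) + drift
        assert gelman_rubin(chains) > 1.1

    def test_agrees_with_arviz_on_stationary_chains(self, rng):
        import arviz as az

        chains = rng.standard_normal((4, 2000)) * 2.0 + 1.0
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 5)))


class TestHPDI:
    def test_point_mass(self):
        assert hpdi(np.full(100, 3.2)) == (3.2, 3.2)

    def test_uniform_integers_window(self):
        lo, hi = hpdi(np.arange(1, 101), 0.95)
        assert hi - lo == 95  # 96 consecutive integers

    def test_exponential_hugs_zero(self, rng):
        x = rng.exponential(size=100_000)
        lo, hi = hpdi(x, 0.95)
        assert lo == pytest.approx(x.min(), abs=1e-3)
        assert hi < np.quantile(x, 0.975)

    def test_never_wider_than_equal_tailed(self, rng):
        for x in (rng.standard_normal(5000), rng.exponential(size=5000),
                  rng.beta(2, 5, 5000)):
            lo, hi = hpdi(x, 0.9)
            q_lo, q_hi = np.quantile(x, [0.05, 0.95])
            assert (hi - lo) <= (q_hi - q_lo) + 1e-12

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(100), 1.5)


class TestSignProbability:
    def test_all_positive(self):
        assert sign_probability([1.0, 2.0, 3.0]) == 1.0

    def test_three_of_four(self):
        assert sign_probability([-1.0, 1.0, 1.0, 1.0]) == 0.75

    def test_symmetric_normal_near_half(self, rng):
        assert sign_probability(rng.standard_normal(100_000)) == pytest.approx(
            0.5, abs=0.01
        )

    def test_negative_mean_counts_negatives(self):
        assert sign_probability([-2.0, -1.0, 1.0]) == pytest.approx(2 / 3)

    def test_zero_mean_warns(self):
        with pytest.warns(UserWarning):
            sign_probability([-1.0, 1.0])


class _StdNormalTarget(Model):
    def scalar_specs(self):
        return [ParamSpec("x", step=1.0)]

    def init_state(self, rng, jitter):
        return {"x": jitter * rng.standard_normal()}

    def logp(self, state):
        return -0.5 * state["x"] ** 2


class _ConjugateNormal(Model):
    """y_i ~ N(theta, 1), theta ~ N(0, 4): posterior is closed-form."""

    def __init__(self, y):
        self.y = np.asarray(y)

    def scalar_specs(self):
        return [ParamSpec("theta", step=0.5)]

    def init_state(self, rng, jitter):
        return {"theta": jitter * rng.standard_normal()}

    def logp(self, state):
        th = state["theta"]
        return -0.5 * np.sum((self.y - th) ** 2) - 0.5 * th * th / 4.0

    def posterior_moments(self):
        n = self.y.size
        prec = n + 1 / 4.0
        return float(self.y.sum() / prec), float(1 / np.sqrt(prec))


class TestEngine:
    def test_standard_normal_target(self):
        cfg = MCMCConfig(n_chains=3, n_iterations=12_000, n_burnin=2_000,
                         seed=5)
        post = run_mcmc(_StdNormalTarget(), cfg)
        s = post.summary()
        assert s.loc["x", "rhat"] < 1.01
        x = post.stacked("x")
        assert np.mean(x) == pytest.approx(0.0, abs=3 / np.sqrt(s.loc["x", "ess"]))
        assert np.std(x) == pytest.approx(1.0, abs=0.05)

    def test_conjugate_normal_matches_closed_form(self, rng):
        y = rng.normal(2.0, 1.0, size=20)
        model = _ConjugateNormal(y)
        mean, sd = model.posterior_moments()
        cfg = MCMCConfig(n_chains=3, n_iterations=8_000, n_burnin=2_000, seed=8)
        post = run_mcmc(model, cfg)
        th = post.stacked("theta")
        mcse = sd / np.sqrt(post.summary().loc["theta", "ess"])
        assert np.mean(th) == pytest.approx(mean, abs=2 * mcse + 2e-3)
        assert np.std(th) == pytest.approx(sd, rel=0.1)

    def test_seeded_determinism(self):
        cfg_data = nf.default_scenario(seed=3)
        cfg_data.n_individuals = 30
        pairs = nf.simulate_fidelity_data(cfg_data)
        prior = DailySurvivalPrior.neutral(cfg_data.years)
        mc = MCMCConfig(n_chains=2, n_iterations=300, n_burnin=150, seed=9)
        a = fit_fidelity(pairs, prior, mc)
        b = fit_fidelity(pairs, prior, mc)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_different_seeds_differ(self):
        cfg_data = nf.default_scenario(seed=3)
        cfg_data.n_individuals = 30
        pairs = nf.simulate_fidelity_data(cfg_data)
        prior = DailySurvivalPrior.neutral(cfg_data.years)
        a = fit_fidelity(pairs, prior,
                         MCMCConfig(n_chains=2, n_iterations=300,
                                    n_burnin=150, seed=9))
        b = fit_fidelity(pairs, prior,
                         MCMCConfig(n_chains=2, n_iterations=300,
                                    n_burnin=150, seed=10))
        assert not np.array_equal(a.draws["mu"], b.draws["mu"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iterations=100, n_burnin=100)
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)


class TestLatentFateFullConditional:
    def test_matches_enumeration_oracle(self):
        # one pair with missing fate and a near-degenerate beta prior:
        # the Gibbs update frequency must match the analytic posterior
        # p(f=1) ~ p_fail * t1(logd) / [p_fail*t1 + (1-p_fail)*t0]
        pair = nf.EncounterPair(
            individual_id="a", year_j=2005, dispersal_m=250.0,
            prev_fate=None, flood_prev=0, spring_index=0.0,
            prev_last_check_age=28,
        )
        prior = DailySurvivalPrior.neutral([2004, 2005], mean=0.9, sd=1e-4)
        model = FidelityMCMC([pair], prior)
        state = model.init_state(np.random.default_rng(0), 0.0)
        state.update(mu=np.log(125.5), beta_f=0.506, beta_fxw=0.0,
                     eta_s=0.0, eta_w=0.0, sigma_ind=0.0, sigma_yr=0.0,
                     sigma_0=0.8, sigma_1=0.8,
                     log_kappa_0=np.log(3.0), log_kappa_1=np.log(3.0))
        rng = np.random.default_rng(1)
        n, hits = 4000, 0
        for _ in range(n):
            model.resample_latents(state, rng)
            hits += int(state["f"][0] == 1)
        p_fail = 1 - 0.9  # last check at age 28: one remaining day
        logd = np.log(250.0)
        t1 = np.exp(nf.t_log_density(logd, np.log(125.5) + 0.506, 0.8, 3.0))
        t0 = np.exp(nf.t_log_density(logd, np.log(125.5), 0.8, 3.0))
        expected = p_fail * t1 / (p_fail * t1 + (1 - p_fail) * t0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert hits / n == pytest.approx(expected, abs=4 * se)


@pytest.fixture(scope="module")
def prior_only_fidelity():
    prior = DailySurvivalPrior.neutral([2000])
    cfg = MCMCConfig(n_chains=3, n_iterations=12_000, n_burnin=2_000, seed=21)
    return fit_fidelity([], prior, cfg)


class TestPriorRecovery:
    """With no data the posterior must reproduce the priors."""

    def test_coefficient_prior_reproduced(self, prior_only_fidelity):
        # beta_f prior: normal with mean 0, SD 10
        x = prior_only_fidelity.stacked("beta_f")
        ess = prior_only_fidelity.summary().loc["beta_f", "ess"]
        assert np.mean(x) == pytest.approx(0.0, abs=4 * 10 / np.sqrt(ess))
        assert np.std(x) == pytest.approx(10.0, rel=0.1)

    def test_scale_prior_reproduced(self, prior_only_fidelity):
        # sigma_ind prior: uniform(0, 3)
        x = prior_only_fidelity.stacked("sigma_ind")
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(x, q) == pytest.approx(3 * q, abs=0.15)

    def test_kappa_prior_reproduced(self, prior_only_fidelity):
        # kappa prior: gamma(1,1) = exponential(1)
        k = np.exp(prior_only_fidelity.stacked("log_kappa_0"))
        assert np.median(k) == pytest.approx(np.log(2), abs=0.08)

    def test_survival_intercept_prior_uniform_on_probability(self):
        # delta ~ logistic(0,1) means inverse-logit(delta) ~ uniform(0,1)
        prior = DailySurvivalPrior.neutral([2000])
        cfg = MCMCConfig(n_chains=3, n_iterations=12_000, n_burnin=2_000,
                         seed=22)
        post = fit_survival([], [], prior, cfg)
        u = 1.0 / (1.0 + np.exp(-post.stacked("delta")))
        for q in np.linspace(0.1, 0.9, 9):
            assert np.quantile(u, q) == pytest.approx(q, abs=0.05)


class TestPosteriorChainsContainer:
    def test_summary_recomputable_and_tidy_export(self, small_fidelity_fit):
        s = small_fidelity_fit.summary()
        assert {"median", "hpdi_lo", "hpdi_hi", "rho", "rhat", "ess"} <= set(
            s.columns
        )
        mu = small_fidelity_fit.stacked("mu")
        assert s.loc["mu", "median"] == pytest.approx(float(np.median(mu)))
        tidy = small_fidelity_fit.to_tidy_frame()
        assert set(tidy.columns) == {"chain", "iteration", "parameter", "value"}
        sub = tidy[tidy.parameter == "mu"]
        assert len(sub) == mu.size

    def test_hpdi_matches_own_summary(self, small_fidelity_fit):
        s = small_fidelity_fit.summary()
        lo, hi = hpdi(small_fidelity_fit.stacked("beta_f"), 0.95)
        assert s.loc["beta_f", "hpdi_lo"] == pytest.approx(lo)
        assert s.loc["beta_f", "hpdi_hi"] == pytest.approx(hi)
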