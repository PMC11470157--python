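"""Fidelity model likelihood pieces: linear predictor, log-t density,
missing-fate submodel, beta priors, expected dispersal."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import nestfidelity as nf
from nestfidelity.data_model import EncounterPair
from nestfidelity.fidelity import (
    DailySurvivalPrior,
    FidelityParams,
    beta_prior_from_moments,
    expected_dispersal,
    fidelity_loglik,
    linear_predictor_g,
    missing_fate_prob,
    t_log_density,
)
from nestfidelity.inference import PosteriorChains


def pair(f=0, w=0, s=0.0, d=100.0, ind="a", year=2005):
    return EncounterPair(
        individual_id=ind, year_j=year, dispersal_m=d, prev_fate=f,
        flood_prev=w, spring_index=s,
    )


class TestLinearPredictor:
    def test_baseline_is_mu(self):
        p = FidelityParams(mu=4.0)
        assert linear_predictor_g(pair(), p) == pytest.approx(4.0)

    def test_fate_effect_scales_dispersal_by_exp_beta(self):
        p = FidelityParams(mu=4.0, beta_f=0.506)
        g0 = linear_predictor_g(pair(f=0), p)
        g1 = linear_predictor_g(pair(f=1), p)
        assert np.exp(g1 - g0) == pytest.approx(1.659, abs=0.001)

    def test_flood_and_interaction_algebra(self):
        p = FidelityParams(
            mu=4.0, beta_f=0.5, beta_fxw=-0.6, eta_w=0.3, eta_s=-0.002
        )
        g = linear_predictor_g(pair(f=1, w=1), p)
        assert g == pytest.approx(4.0 + 0.3 + 0.5 - 0.6)

    def test_random_effects_enter_additively(self):
        p = FidelityParams(mu=4.0)
        p.eps_ind["a"] = 0.25
        p.eps_yr[2005] = -0.1
        assert linear_predictor_g(pair(), p) == pytest.approx(4.15)

    def test_missing_fate_rejected(self):
        p = FidelityParams()
        with pytest.raises(ValueError):
            linear_predictor_g(pair(f=None), p)


class TestTLogDensity:
    def test_cauchy_peak(self):
        assert t_log_density(0, 0, 1, 1) == pytest.approx(np.log(1 / np.pi))

    def test_normal_limit_at_large_df(self):
        for x in (-2.0, 0.0, 2.0):
            assert t_log_density(x, 0.5, 1.3, 1e6) == pytest.approx(
                stats.norm.logpdf(x, 0.5, 1.3), abs=1e-4
            )

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda x: np.exp(t_log_density(x, 1.0, 2.0, 3.0)),
            -np.inf, np.inf,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_location_scale_t(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal()
            loc = rng.normal()
            scale = rng.uniform(0.1, 3)
            df = rng.uniform(0.5, 50)
            assert t_log_density(x, loc, scale, df) == pytest.approx(
                stats.t.logpdf(x, df, loc=loc, scale=scale), abs=1e-10
            )

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            t_log_density(0, 0, 0.0, 1)
        with pytest.raises(ValueError):
            t_log_density(0, 0, 1, -1)


class TestFidelityLoglik:
    def test_single_pair_at_mode(self):
        p = FidelityParams(mu=np.log(100.0), sigma_resid=(0.8, 0.9),
                           kappa=(3.0, 4.0))
        ll = fidelity_loglik([pair(d=100.0)], p, [0])
        assert ll == pytest.approx(float(t_log_density(0, 0, 0.8, 3.0)))

    def test_additivity_over_pairs(self):
        p = FidelityParams(mu=4.5, beta_f=0.5, sigma_resid=(0.7, 1.1),
                           kappa=(2.0, 5.0))
        p1, p2 = pair(d=80.0), pair(f=1, d=300.0, ind="b")
        assert fidelity_loglik([p1, p2], p, [0, 1]) == pytest.approx(
            fidelity_loglik([p1], p, [0]) + fidelity_loglik([p2], p, [1])
        )

    def test_matches_term_by_term_transcription(self):
        # brute-force oracle: literal per-pair evaluation with scipy's t
        rng = np.random.default_rng(99)
        params = FidelityParams(
            mu=4.8, beta_f=0.5, beta_fxw=-0.6, eta_s=-0.002, eta_w=0.31,
            sigma_ind=0.68, sigma_yr=0.08,
            sigma_resid=(0.8, 0.55), kappa=(3.0, 2.0),
        )
        pairs, fates = [], []
        for i in range(40):
            ind = f"i{i % 7}"
            yr = 2000 + int(rng.integers(0, 17))
            params.eps_ind.setdefault(ind, float(rng.normal(0, 0.68)))
            params.eps_yr.setdefault(yr, float(rng.normal(0, 0.08)))
            pairs.append(pair(
                f=int(rng.integers(0, 2)), w=int(rng.integers(0, 2)),
                s=float(rng.normal(0, 3)), d=float(rng.lognormal(4.8, 1)),
                ind=ind, year=yr,
            ))
            fates.append(pairs[-1].prev_fate)
        expected = 0.0
        for q, f in zip(pairs, fates):
            g = (params.mu + params.eta_s * q.spring_index
                 + params.eta_w * q.flood_prev + params.eps_yr[q.year_j]
                 + params.beta_f * f + params.beta_fxw * f * q.flood_prev
                 + params.eps_ind[q.individual_id])
            expected += stats.t.logpdf(
                np.log(max(q.dispersal_m, 1.0)), params.kappa[f],
                loc=g, scale=params.sigma_resid[f],
            )
        assert fidelity_loglik(pairs, params, fates) == pytest.approx(
            expected, abs=1e-10
        )


class TestMissingFateProb:
    def test_perfect_survival_never_fails(self):
        assert missing_fate_prob(1, np.ones(28)) == 0.0

    def test_single_remaining_day(self):
        assert missing_fate_prob(28, np.array([0.99])) == pytest.approx(0.01)

    def test_two_remaining_days(self):
        assert missing_fate_prob(27, np.full(2, 0.99)) == pytest.approx(
            1 - 0.99**2
        )

    def test_monotone_nonincreasing_in_last_check_age(self):
        phi_full = np.full(28, 0.97)
        probs = [
            missing_fate_prob(m, phi_full[m - 1 :]) for m in range(1, 29)
        ]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_overlong_age_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = missing_fate_prob(30, np.array([0.95]))
        assert out == pytest.approx(0.05)


class TestBetaPriorFromMoments:
    def test_uniform_moments_give_uniform(self):
        a, b = beta_prior_from_moments(0.5, np.sqrt(1 / 12))
        assert (a, b) == pytest.approx((1.0, 1.0))

    @pytest.mark.parametrize("mean, sd", [(0.994, 0.003), (0.3, 0.1),
                                          (0.99, 0.005)])
    def test_round_trips_mean_and_sd(self, mean, sd):
        a, b = beta_prior_from_moments(mean, sd)
        assert stats.beta.mean(a, b) == pytest.approx(mean)
        assert stats.beta.std(a, b) == pytest.approx(sd)

    def test_infeasible_moments_error(self):
        with pytest.raises(ValueError):
            beta_prior_from_moments(0.9, 0.3)


class TestDailySurvivalPrior:
    def test_neutral_prior_moments(self):
        prior = DailySurvivalPrior.neutral([2000, 2001])
        a, b = prior.alpha[0, 0], prior.beta[0, 0]
        assert stats.beta.mean(a, b) == pytest.approx(0.99)
        assert stats.beta.std(a, b) == pytest.approx(0.005)

    def test_table_with_missing_year_falls_back_to_age_means(self):
        df = pd.DataFrame(
            {
                "age": list(range(1, 29)) * 2,
                "year": [2000] * 28 + [2001] * 28,
                "mean": [0.98] * 28 + [0.96] * 28,
                "sd": [0.01] * 56,
            }
        )
        prior = DailySurvivalPrior.from_table(df, [2000, 2001, 2005])
        # 2005 absent: uses the across-year mean 0.97
        a, b = prior.alpha[0, 2], prior.beta[0, 2]
        assert stats.beta.mean(a, b) == pytest.approx(0.97)


def _degenerate_posterior(mu=4.0, beta_f=0.5, n=50):
    """All-identical draws with zero random-effect SDs."""
    base = {
        "mu": mu, "beta_f": beta_f, "beta_fxw": 0.0, "eta_s": 0.0,
        "eta_w": 0.0, "sigma_ind": 0.0, "sigma_yr": 0.0,
        "sigma_0": 0.5, "sigma_1": 0.5, "log_kappa_0": 1.0,
        "log_kappa_1": 1.0,
    }
    draws = {k: np.full((2, n), v) for k, v in base.items()}
    return PosteriorChains(draws)


class TestExpectedDispersal:
    def test_degenerate_posterior_returns_exp_mu(self):
        post = _degenerate_posterior(mu=4.0)
        med, (lo, hi) = expected_dispersal(post, f=0, w=0)
        assert med == pytest.approx(np.exp(4.0))
        assert (lo, hi) == pytest.approx((np.exp(4.0), np.exp(4.0)))

    def test_fate_ratio_is_exp_beta_under_shared_draws(self):
        post = _degenerate_posterior(mu=4.0, beta_f=0.506)
        m0, _ = expected_dispersal(post, 0, 0, np.random.default_rng(1))
        m1, _ = expected_dispersal(post, 1, 0, np.random.default_rng(1))
        assert m1 / m0 == pytest.approx(np.exp(0.506))

    def test_empty_posterior_errors(self):
        post = _degenerate_posterior()
        post.draws = {k: v[:, :0] for k, v in post.draws.items()}
        with pytest.raises(ValueError):
            expected_dispersal(post, 0, 0)

    def test_prediction_accounts_for_random_effect_spread(self, rng):
        base = _degenerate_posterior(mu=4.0)
        spread = {k: v.copy() for k, v in base.draws.items()}
        spread["sigma_ind"] = np.full_like(spread["sigma_ind"], 0.7)
        post = PosteriorChains(spread)
        _, (lo, hi) = expected_dispersal(post, 0, 0, rng)
        assert hi > lo  # among-individual variation widens the interval
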