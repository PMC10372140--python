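import numpy as np
import pytest
from scipy import stats

from kumacens import (
    GammaPriors,
    KumParams,
    LossSpec,
    McmcConfig,
    elicit_hyperparameters,
    equal_tailed_interval,
    generate_pcs2_sample,
    hpd_interval,
    log_conditional_alpha,
    mle_fit,
    point_estimates,
    sample_posterior,
    validate_scheme,
)
from kumacens.bayes_mcmc import PosteriorDraws

from conftest import random_pcs2_sample

PRIORS = GammaPriors(2.0, 1.5, 3.0, 2.0)


def joint_logpost(alpha, beta, sample, priors):
    """Log joint posterior density (up to a constant), written independently."""
    x = sample.observations
    m = sample.m
    R = sample.scheme.removals_array()
    L = np.log(1 - x**alpha)
    return (
        (m + priors.a1 - 1) * np.log(alpha)
        + (m + priors.a2 - 1) * np.log(beta)
        + (alpha - 1) * np.sum(np.log(x))
        - np.sum(L)
        + beta * np.sum((R + 1) * L)
        - priors.b1 * alpha
        - priors.b2 * beta
    )


class TestConditionalAlpha:
    def test_beta_terms_cancel_against_joint(self, small_sample):
        # at fixed beta, differences of the alpha-conditional equal the
        # same differences of the joint posterior
        beta = 1.7
        d_cond = log_conditional_alpha(
            1.2, small_sample, PRIORS, beta
        ) - log_conditional_alpha(0.8, small_sample, PRIORS, beta)
        d_joint = joint_logpost(1.2, beta, small_sample, PRIORS) - joint_logpost(
            0.8, beta, small_sample, PRIORS
        )
        assert d_cond == pytest.approx(d_joint, rel=1e-10)

    def test_hand_evaluation_m2(self):
        s_scheme = validate_scheme(3, 2, (1, 0))
        from kumacens import PCS2Sample

        s = PCS2Sample(np.array([0.3, 0.6]), s_scheme)
        a = 1.5
        hand = (
            (2 + PRIORS.a1 - 1) * np.log(a)
            + (a - 1) * (np.log(0.3) + np.log(0.6))
            - np.log(1 - 0.3**a)
            - np.log(1 - 0.6**a)
            + 2 * np.log(1 - 0.3**a)
            + 1 * np.log(1 - 0.6**a)
            - PRIORS.b1 * a
        )
        assert log_conditional_alpha(a, s, PRIORS) == pytest.approx(hand, rel=1e-12)

    def test_nonpositive_alpha_is_minus_inf(self, small_sample):
        assert log_conditional_alpha(0.0, small_sample, PRIORS) == -np.inf
        assert log_conditional_alpha(-1.0, small_sample, PRIORS) == -np.inf

    def test_increasing_in_prior_shape(self, small_sample):
        lo = log_conditional_alpha(2.0, small_sample, GammaPriors(1, 1, 1, 1))
        hi = log_conditional_alpha(2.0, small_sample, GammaPriors(5, 1, 1, 1))
        assert hi > lo  # +log(alpha) term, alpha > 1


class TestSampler:
    def test_seeded_chains_are_bit_identical(self, small_sample):
        cfg = McmcConfig(500, 100, seed=9)
        d1 = sample_posterior(small_sample, PRIORS, cfg)
        d2 = sample_posterior(small_sample, PRIORS, cfg)
        assert np.array_equal(d1.alpha_chain, d2.alpha_chain)
        assert np.array_equal(d1.beta_chain, d2.beta_chain)

    def test_beta_conditional_moments_match_gamma(self):
        # alpha frozen (zero proposal sd): the beta chain is i.i.d. gamma
        # with shape m+a2 and rate b2 - sum (R+1) log(1-x^alpha)
        sample, _ = random_pcs2_sample(3, n=20, m=15)
        mle = mle_fit(sample)
        cfg = McmcConfig(100_000, 100, proposal_sd=0.0, seed=12)
        draws = sample_posterior(sample, PRIORS, cfg, mle=mle)
        a_hat = mle.estimates.alpha
        R = sample.scheme.removals_array()
        rate = PRIORS.b2 - np.sum(
            (R + 1) * np.log1p(-sample.observations**a_hat)
        )
        shape = sample.m + PRIORS.a2
        chain = draws.beta_chain
        n = len(chain)
        se_mean = np.sqrt(shape / rate**2 / n)
        assert abs(chain.mean() - shape / rate) < 3 * se_mean
        assert chain.var() == pytest.approx(shape / rate**2, rel=0.05)
        assert np.all(draws.alpha_chain == a_hat)  # alpha never moves

    def test_matches_grid_posterior_two_sample(self):
        # independent oracle: draw from the joint posterior by fine-grid
        # inversion on a small instance, compare marginals by K-S
        sample, _ = random_pcs2_sample(8, n=7, m=5)
        priors = PRIORS
        a_grid = np.linspace(0.01, 12, 900)
        b_grid = np.linspace(0.01, 12, 900)
        lp = np.array(
            [joint_logpost(a, b_grid, sample, priors) for a in a_grid]
        )
        w = np.exp(lp - lp.max())
        w /= w.sum()
        rng = np.random.default_rng(77)
        idx = rng.choice(w.size, size=4000, p=w.ravel())
        ia, ib = np.unravel_index(idx, w.shape)
        da = a_grid[1] - a_grid[0]
        oracle_a = a_grid[ia] + rng.uniform(-da / 2, da / 2, size=ia.size)
        oracle_b = b_grid[ib] + rng.uniform(-da / 2, da / 2, size=ib.size)

        cfg = McmcConfig(42_000, 2_000, seed=5, thin=10)
        draws = sample_posterior(sample, priors, cfg)
        mc_a, mc_b = draws.kept()
        assert stats.ks_2samp(mc_a, oracle_a).pvalue > 0.01
        assert stats.ks_2samp(mc_b, oracle_b).pvalue > 0.01

    def test_parameter_recovery(self):
        # posterior SE means over replicates concentrate near the truth
        from kumacens import elicit_from_truth

        truth = KumParams(1.0, 1.0)
        scheme = validate_scheme(80, 60, (20,) + (0,) * 59)
        priors = elicit_from_truth(truth, 2024)  # informative, as elicited
        rng = np.random.default_rng(2024)
        means = []
        for _ in range(200):
            sample = generate_pcs2_sample(truth, scheme, rng)
            cfg = McmcConfig(3000, 1000, seed=int(rng.integers(2**31 - 1)))
            est = point_estimates(sample_posterior(sample, priors, cfg))
            means.append([est.alpha, est.beta])
        avg = np.mean(means, axis=0)
        assert avg[0] == pytest.approx(1.0, rel=0.05)
        assert avg[1] == pytest.approx(1.0, rel=0.05)


class TestPointEstimates:
    def _draws(self, chain):
        chain = np.asarray(chain, dtype=float)
        cfg = McmcConfig(len(chain), 0, seed=0)
        return PosteriorDraws(chain, chain.copy(), 1.0, cfg)

    def test_constant_chain_all_losses_agree(self):
        d = self._draws(np.full(200, 2.0))
        for loss in (LossSpec("SE"), LossSpec("LINEX", c=3), LossSpec("GE", q=2)):
            est = point_estimates(d, loss)
            assert est.alpha == pytest.approx(2.0, rel=1e-12)

    def test_linex_limit_to_se(self):
        rng = np.random.default_rng(1)
        d = self._draws(rng.gamma(5, 0.5, size=5000))
        se = point_estimates(d, LossSpec("SE"))
        linex = point_estimates(d, LossSpec("LINEX", c=1e-8))
        assert linex.alpha == pytest.approx(se.alpha, abs=1e-6)

    def test_two_point_chain_linex_hand_value(self):
        # mean(e^-1, e^-3) = 0.208833; -(1/1) log of it = 1.566219
        d = self._draws([1.0, 3.0] * 100)
        est = point_estimates(d, LossSpec("LINEX", c=1.0))
        assert est.alpha == pytest.approx(-np.log((np.exp(-1) + np.exp(-3)) / 2), rel=1e-12)
        assert est.alpha == pytest.approx(1.566219, abs=1e-6)

    def test_extreme_linex_does_not_overflow(self):
        d = self._draws(np.linspace(0.5, 4.0, 1000))
        est = point_estimates(d, LossSpec("LINEX", c=-800.0))
        assert np.isfinite(est.alpha)
        # huge negative c rewards the chain maximum
        assert est.alpha == pytest.approx(4.0, rel=0.01)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            point_estimates(self._draws(np.ones(50)))


class TestIntervals:
    def test_uniform_grid_hpd(self):
        chain = np.linspace(0.0, 1.0, 101)
        ci = hpd_interval(chain, 0.95)
        assert ci.width == pytest.approx(0.95, abs=1e-12)
        assert ci.lower == 0.0  # all windows tie; leftmost wins

    def test_normal_hpd_matches_analytic(self):
        rng = np.random.default_rng(8)
        chain = rng.standard_normal(100_000)
        ci = hpd_interval(chain, 0.95)
        assert ci.lower == pytest.approx(-1.96, abs=0.05)
        assert ci.upper == pytest.approx(1.96, abs=0.05)

    @pytest.mark.parametrize("shape,scale", [(2, 1), (0.8, 2.0), (5, 0.3)])
    def test_hpd_no_wider_than_equal_tailed(self, shape, scale):
        rng = np.random.default_rng(int(shape * 10))
        chain = rng.gamma(shape, scale, size=20_000)
        hpd = hpd_interval(chain, 0.95)
        eq = equal_tailed_interval(chain, 0.95)
        assert hpd.width <= eq.width + 1e-12

    def test_rejects_bad_level(self):
        with pytest.raises(ValueError):
            hpd_interval(np.ones(200), 1.2)


class TestElicitation:
    def test_hand_value(self):
        # past alpha MLEs with mean 2 and variance 0.5 -> a1=8, b1=4
        priors = elicit_hyperparameters([1.5, 2.5], [1.0, 3.0])
        assert priors.a1 == pytest.approx(8.0)
        assert priors.b1 == pytest.approx(4.0)
        assert priors.a2 == pytest.approx(2.0)
        assert priors.b2 == pytest.approx(1.0)

    def test_moment_match_is_exact(self):
        rng = np.random.default_rng(4)
        past_a = rng.gamma(3, 2, size=50)
        past_b = rng.gamma(2, 1, size=50)
        priors = elicit_hyperparameters(past_a, past_b)
        assert priors.a1 / priors.b1 == pytest.approx(past_a.mean(), rel=1e-12)
        assert priors.a1 / priors.b1**2 == pytest.approx(past_a.var(ddof=1), rel=1e-12)
        assert priors.a2 / priors.b2 == pytest.approx(past_b.mean(), rel=1e-12)
        assert priors.a2 / priors.b2**2 == pytest.approx(past_b.var(ddof=1), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            elicit_hyperparameters([2.0, 2.0], [1.0, 3.0])
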