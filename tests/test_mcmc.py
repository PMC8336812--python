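"""Sampler correctness: conjugate updates, MH targets, variance draws,
reproducibility."""

import numpy as np
import pytest
from scipy.special import gammaln

from distreg.bases import PenaltyMatrix, build_difference_penalty
from distreg.evaluate import effective_sample_size
from distreg.mcmc import (
    SamplerConfig,
    gibbs_update_mu_block,
    load_chain,
    mh_update_sigma_block,
    run_mcmc,
    save_chain,
    update_variance_parameter,
)
from distreg.model import SmoothBlock, assemble, make_model_grid


def _linear_block(X, penalty=None, name="b"):
    return SmoothBlock(name, np.asarray(X, dtype=float), penalty,
                       meta={"kind": "linear", "colnames": []})


class TestGibbsUpdate:
    def test_flat_prior_limit_matches_gls(self, rng):
        # fixed effects, heteroscedastic noise: posterior mean equals the
        # generalised-least-squares estimate
        n, p = 200, 3
        X = rng.normal(size=(n, p))
        beta_true = np.array([1.0, -2.0, 0.5])
        sigma = np.exp(rng.uniform(-0.5, 0.5, n))
        y = X @ beta_true + sigma * rng.standard_normal(n)
        W = np.diag(1.0 / sigma**2)
        gls = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        blk = _linear_block(X)
        draws = np.array([
            gibbs_update_mu_block(blk, y, sigma, None, rng) for _ in range(4000)
        ])
        post_cov = np.linalg.inv(X.T @ W @ X)
        se = np.sqrt(np.diag(post_cov) / 4000)
        assert np.all(np.abs(draws.mean(axis=0) - gls) < 5 * se)

    def test_ridge_shrinkage_closed_form(self, rng):
        # K = I, B = I, sigma = 1: conditional mean is y / (1 + 1/gamma^2)
        n = 6
        y = rng.normal(size=n)
        gamma2 = 0.7
        blk = _linear_block(np.eye(n),
                            PenaltyMatrix(matrix=np.eye(n), rank_deficiency=0))
        draws = np.array([
            gibbs_update_mu_block(blk, y, np.ones(n), gamma2, rng)
            for _ in range(6000)
        ])
        expected = y / (1.0 + 1.0 / gamma2)
        se = np.sqrt(1.0 / (1.0 + 1.0 / gamma2) / 6000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 5 * se)

    def test_seeded_determinism(self):
        blk = _linear_block(np.ones((10, 1)))
        y = np.arange(10.0)
        d1 = gibbs_update_mu_block(blk, y, np.ones(10), None,
                                   np.random.default_rng(7))
        d2 = gibbs_update_mu_block(blk, y, np.ones(10), None,
                                   np.random.default_rng(7))
        assert np.array_equal(d1, d2)

    def test_all_zero_design_errors(self, rng):
        blk = _linear_block(np.zeros((10, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            gibbs_update_mu_block(blk, np.zeros(10), np.ones(10), None, rng)


class TestMHSigmaUpdate:
    @pytest.mark.parametrize("mode", ["iwls", "random-walk"])
    def test_posterior_sigma_matches_conjugate(self, mode):
        # mu known (= 0): posterior of the variance is inverse-gamma
        # IG(n/2, S/2) under the flat prior on eta = log sigma; compare the
        # posterior mean of sigma = exp(eta) with the closed-form moment
        rng = np.random.default_rng(3)
        n, sigma_true = 400, 1.5
        y = rng.normal(0.0, sigma_true, n)
        S = float(np.sum(y**2))
        exact = np.exp(
            0.5 * np.log(S / 2.0) + gammaln((n - 1) / 2.0) - gammaln(n / 2.0)
        )
        blk = _linear_block(np.ones((n, 1)))
        coef = np.array([np.log(y.std())])
        draws = []
        for _ in range(4000):
            coef, _acc = mh_update_sigma_block(
                blk, y, coef, None, np.zeros(n), rng,
                proposal_mode=mode, rw_scale=1.0,
            )
            draws.append(np.exp(coef[0]))
        draws = np.array(draws[500:])
        mcse = draws.std(ddof=1) / np.sqrt(effective_sample_size(draws))
        assert abs(draws.mean() - exact) < 4 * mcse

    def test_zero_step_random_walk_always_accepts(self, rng):
        blk = _linear_block(np.ones((20, 1)))
        coef = np.array([0.3])
        accs = []
        for _ in range(50):
            new, acc = mh_update_sigma_block(
                blk, rng.normal(size=20), coef, None, np.zeros(20), rng,
                proposal_mode="random-walk", rw_scale=0.0,
            )
            accs.append(acc)
            assert np.array_equal(new, coef)
        assert all(accs)

    def test_reversibility_two_set_flow_balance(self):
        # reversible kernels have equal empirical probability flow between
        # any two sets; split the state space at the target median
        rng = np.random.default_rng(11)
        n = 30
        y = rng.normal(0.0, 1.3, n)
        blk = _linear_block(np.ones((n, 1)))
        coef = np.array([0.0])
        trace = np.empty(120_000)
        for i in range(trace.size):
            coef, _ = mh_update_sigma_block(
                blk, y, coef, None, np.zeros(n), rng,
                proposal_mode="random-walk", rw_scale=1.0,
            )
            trace[i] = coef[0]
        cut = np.median(trace)
        a = trace[:-1] <= cut
        b = trace[1:] <= cut
        n_ab = np.sum(a & ~b)
        n_ba = np.sum(~a & b)
        flow = (n_ab - n_ba) / max(n_ab + n_ba, 1)
        assert abs(flow) < 0.02

    def test_nonfinite_residuals_error(self, rng):
        blk = _linear_block(np.ones((5, 1)))
        with pytest.raises(ValueError):
            mh_update_sigma_block(blk, np.array([1.0, np.inf, 0, 0, 0]),
                                  np.zeros(1), None, np.zeros(5), rng)


class TestVarianceUpdate:
    def test_null_space_beta_gives_prior(self, rng):
        pen = build_difference_penalty(8, 2)
        beta = 3.0 + 0.5 * np.arange(8.0)  # linear => K beta = 0
        a, b = 2.5, 1.5
        draws = np.array([
            update_variance_parameter(beta, pen, a, b, rng) for _ in range(20000)
        ])
        # prior IG(a + rank/2, b): mean b / (a + rank/2 - 1)
        a_post = a + pen.rank / 2.0
        expected = b / (a_post - 1.0)
        assert abs(draws.mean() - expected) / expected < 0.05

    def test_long_run_mean_matches_inverse_gamma(self, rng):
        pen = build_difference_penalty(6, 1)
        beta = rng.normal(size=6)
        a, b = 2.0, 1.0
        quad = beta @ pen.matrix @ beta
        a_post, b_post = a + pen.rank / 2.0, b + quad / 2.0
        draws = np.array([
            update_variance_parameter(beta, pen, a, b, rng) for _ in range(20000)
        ])
        expected = b_post / (a_post - 1.0)
        assert abs(draws.mean() - expected) / expected < 0.05

    def test_rank_is_n_minus_order(self):
        assert build_difference_penalty(13, 2).rank == 11

    def test_corrupted_penalty_errors(self, rng):
        bad = PenaltyMatrix(matrix=-np.eye(3), rank_deficiency=0)
        with pytest.raises(ValueError):
            update_variance_parameter(np.ones(3), bad, 1.0, 1.0, rng)


class TestRunMcmc:
    @pytest.fixture(scope="class")
    def toy_model(self):
        import pandas as pd

        from distreg.model import assemble, make_model_grid

        rng = np.random.default_rng(5)
        n = 500
        df = pd.DataFrame({
            "haz": rng.normal(2.0, 1.5, n),
            "gender": "female",
            "urban": "rural",
            "wave": "2013/14",
        })
        spec = make_model_grid()[3]  # linear terms only
        return assemble(spec, df, None), df

    def test_intercept_only_recovery(self, toy_model):
        am, df = toy_model
        chain = run_mcmc(am, SamplerConfig(seed=9, iterations=2500,
                                           burn_in=500, thinning=2))
        mu_tr = chain.coefficients[("mu", "linear_mu")][:, 0]
        sd_tr = np.exp(chain.coefficients[("sigma", "linear_sigma")][:, 0])
        for tr, truth in ((mu_tr, 2.0), (sd_tr, 1.5)):
            mcse = tr.std(ddof=1) / np.sqrt(effective_sample_size(tr))
            post_sd = tr.std(ddof=1)
            # truth lies within posterior uncertainty + MC error
            assert abs(tr.mean() - truth) < 3 * post_sd + 3 * mcse

    def test_doubling_iterations_reproduces_first_half(self, toy_model):
        am, _ = toy_model
        c1 = run_mcmc(am, SamplerConfig(seed=21, iterations=300, burn_in=100,
                                        thinning=2))
        c2 = run_mcmc(am, SamplerConfig(seed=21, iterations=500, burn_in=100,
                                        thinning=2))
        k = ("mu", "linear_mu")
        n1 = c1.coefficients[k].shape[0]
        assert np.array_equal(c1.coefficients[k], c2.coefficients[k][:n1])

    def test_random_walk_acceptance_in_tuning_band(self, small_survey, lattice5):
        table, _, _ = small_survey
        spec = make_model_grid(n_intervals=8, tensor_intervals=4)[1]
        am = assemble(spec, table, lattice5[0])
        chain = run_mcmc(am, SamplerConfig(
            seed=2, iterations=500, burn_in=250, thinning=2,
            proposal_mode="random-walk",
        ))
        for name, rate in chain.acceptance.items():
            assert 0.1 <= rate <= 0.9, (name, rate)

    def test_chain_roundtrip(self, toy_model, tmp_path):
        am, _ = toy_model
        chain = run_mcmc(am, SamplerConfig(seed=3, iterations=120, burn_in=40,
                                           thinning=4))
        save_chain(chain, tmp_path / "chain")
        back = load_chain(tmp_path / "chain")
        assert back.config == chain.config
        for k, v in chain.coefficients.items():
            assert np.allclose(back.coefficients[k], v)
        assert np.allclose(back.pointwise_loglik, chain.pointwise_loglik)
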