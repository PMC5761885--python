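"""The cumulative-link mixed model: likelihood, gradient, limits, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from beatgrid.clmm import (
    ClmmSpec,
    _ClmmProblem,
    empirical_thresholds,
    fit_clmm,
    loglik_by_quadrature,
)
from conftest import simulate_clmm_data


def brute_force_loglik(y, X, groups, theta, beta, sigma, num=40001, span=10.0):
    """Dense-trapezoid integration of the marginal likelihood (oracle)."""
    theta = np.asarray(theta, dtype=float)
    K = theta.size + 1
    bgrid = np.linspace(-span * sigma, span * sigma, num)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        eta = (X[sel] @ beta)[:, None] + bgrid[None, :]
        up = np.where(y[sel][:, None] < K - 1,
                      theta[np.minimum(y[sel], K - 2)][:, None], np.inf) - eta
        lo = np.where(y[sel][:, None] > 0,
                      theta[np.maximum(y[sel] - 1, 0)][:, None], -np.inf) - eta
        p = special.expit(up) - special.expit(lo)
        integrand = np.exp(np.log(p).sum(axis=0)) * stats.norm.pdf(bgrid, scale=sigma)
        total += np.log(np.trapezoid(integrand, bgrid))
    return total


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(3)
    beta = np.array([0.8, -0.5])
    theta = np.array([-1.0, 0.0, 0.8, 1.7])
    y, X, groups = simulate_clmm_data(rng, 3, 10, beta, theta, 0.7)
    return y, X, groups, beta, theta, 0.7


class TestLikelihood:
    def test_quadrature_matches_dense_integration(self, toy):
        y, X, groups, beta, theta, sigma = toy
        oracle = brute_force_loglik(y, X, groups, theta, beta, sigma)
        ll = loglik_by_quadrature(y, X, groups, 5, beta, theta, sigma, nodes=15)
        assert ll == pytest.approx(oracle, rel=5e-7)

    def test_laplace_is_single_node(self, toy):
        y, X, groups, beta, theta, sigma = toy
        oracle = brute_force_loglik(y, X, groups, theta, beta, sigma)
        lap = loglik_by_quadrature(y, X, groups, 5, beta, theta, sigma, nodes=1)
        assert lap == pytest.approx(oracle, rel=1e-2)
        assert abs(lap - oracle) > 0  # approximate, not exact

    def test_analytic_gradient_matches_finite_differences(self, toy):
        y, X, groups, beta, theta, sigma = toy
        prob = _ClmmProblem(y, X, groups, 5, nodes=15)
        psi = prob.pack(beta, theta, sigma)
        _, g = prob.loglik_grad(psi)
        num = np.empty_like(psi)
        for i in range(psi.size):
            e = np.zeros_like(psi)
            e[i] = 1e-6
            num[i] = (prob.loglik_grad(psi + e, False)[0]
                      - prob.loglik_grad(psi - e, False)[0]) / 2e-6
        assert np.allclose(g, num, atol=1e-6)

    def test_probabilities_sum_to_one(self, toy):
        y, X, groups, beta, theta, sigma = toy
        prob = _ClmmProblem(y, X, groups, 5)
        eta = X @ beta
        total = np.zeros(len(y))
        for k in range(5):
            p2 = _ClmmProblem(np.full_like(y, k), X, groups, 5)
            u, lo = p2._bounds(theta, eta, 0.0)
            logp, *_ = p2._logp_terms(u, lo)
            total += np.exp(logp)
        assert np.allclose(total, 1.0)

    def test_invariant_to_participant_relabeling_and_order(self, toy):
        y, X, groups, beta, theta, sigma = toy
        ll = loglik_by_quadrature(y, X, groups, 5, beta, theta, sigma)
        perm = np.random.default_rng(0).permutation(len(y))
        relabel = (groups.max() - groups)[perm]
        ll2 = loglik_by_quadrature(y[perm], X[perm], relabel, 5, beta, theta, sigma)
        assert ll2 == pytest.approx(ll, abs=1e-9)

    def test_quadrature_converged_by_15_nodes(self):
        """On a default-preset-sized problem the 15- and 25-node marginal
        log-likelihoods differ by less than 1e-4."""
        rng = np.random.default_rng(8)
        theta = np.array([-0.2, 0.9, 1.7, 2.4, 3.0, 3.6, 4.2, 4.9, 5.7])
        beta = np.array([1.0, 0.4])
        y, X, groups = simulate_clmm_data(rng, 32, 170, beta, theta, 1.0)
        l15 = loglik_by_quadrature(y, X, groups, 10, beta, theta, 1.0, nodes=15)
        l25 = loglik_by_quadrature(y, X, groups, 10, beta, theta, 1.0, nodes=25)
        assert abs(l15 - l25) < 1e-4


def ratings_frame(y, groups, X=None):
    df = pd.DataFrame({"participant_id": groups, "rating": y + 1})
    return df


class TestFitting:
    def test_null_model_thresholds_equal_cumulative_logodds(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 6, size=400)
        df = ratings_frame(y, np.zeros(400, dtype=int))
        fit = fit_clmm(df, spec=ClmmSpec(sigma_fixed=0.0),
                       X=np.zeros((400, 0)), column_names=[])
        counts = np.bincount(y, minlength=6)
        cum = np.cumsum(counts)[:-1] / 400
        expected = np.log(cum / (1 - cum))
        assert np.allclose(fit.theta, expected, atol=1e-6)

    def test_sigma_to_zero_limit_matches_fixed_effect_fit(self, toy):
        y, X, groups, *_ = toy
        df = ratings_frame(y, groups)
        fixed = fit_clmm(df, spec=ClmmSpec(sigma_fixed=0.0), X=X,
                         column_names=["x1", "x2"])
        tiny = fit_clmm(df, spec=ClmmSpec(sigma_fixed=1e-6), X=X,
                        column_names=["x1", "x2"])
        assert np.allclose(tiny.beta, fixed.beta, atol=1e-4)
        assert np.allclose(tiny.theta, fixed.theta, atol=1e-4)
        assert tiny.loglik == pytest.approx(fixed.loglik, abs=1e-6)

    def test_fixed_effect_fit_agrees_with_statsmodels(self, toy):
        """Independent route: statsmodels' ordinal regression on the same
        data reproduces the sigma-free cumulative-logit fit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, X, groups, *_ = toy
        df = ratings_frame(y, groups)
        ours = fit_clmm(df, spec=ClmmSpec(sigma_fixed=0.0), X=X,
                        column_names=["x1", "x2"])
        sm_fit = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert np.allclose(ours.beta, sm_fit.params[:2], atol=1e-3)

    def test_collapsed_extreme_categories_map_back(self):
        rng = np.random.default_rng(2)
        y = rng.integers(2, 5, size=300)  # ratings 3..5 of a 1..10 scale
        df = pd.DataFrame({"participant_id": np.repeat(np.arange(6), 50),
                           "rating": y + 1})
        fit = fit_clmm(df, spec=ClmmSpec(sigma_fixed=0.0),
                       X=np.zeros((300, 0)), column_names=[])
        assert list(fit.category_levels) == [3, 4, 5]
        assert fit.theta.size == 2

    def test_recovery_on_one_simulated_dataset(self):
        rng = np.random.default_rng(21)
        beta = np.array([1.0, 0.6, -0.3])
        theta = np.linspace(-0.5, 4.5, 9)
        y, X, groups = simulate_clmm_data(rng, 30, 120, beta, theta, 0.9)
        df = ratings_frame(y, groups)
        fit = fit_clmm(df, spec=ClmmSpec(nodes=15), X=X,
                       column_names=["a", "b", "c"])
        z = (fit.beta - beta) / fit.se_beta
        assert np.all(np.abs(z) < 3.5)
        assert abs(fit.sigma_b - 0.9) < 3.5 * fit.se_sigma_b

    def test_single_category_rejected(self):
        df = pd.DataFrame({"participant_id": [0, 0, 1, 1], "rating": [2] * 4})
        with pytest.raises(ValueError, match="two observed rating"):
            fit_clmm(df, X=np.zeros((4, 0)), column_names=[])
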