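"""OU covariance, marginal likelihood and GP posterior algebra."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import phylogp as pg
from phylogp.kernel import gp_posterior

from conftest import random_gamma


class TestHyperParams:
    def test_derived_accessors(self):
        g = pg.HyperParams(2.5, 6.17, 0.5)
        assert g.alpha == pytest.approx(1.0 / (2 * 6.17))
        assert g.phylo_fraction == pytest.approx(6.25 / 6.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            pg.HyperParams(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            pg.HyperParams(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            pg.HyperParams(1.0, None, 0.5)  # ell None needs sigma_f == 0
        assert pg.HyperParams(0.0, None, 1.0).sigma_n == 1.0


class TestOUCov:
    @pytest.mark.parametrize(
        "gamma,d,same,expected",
        [
            ((2.5, 6.17, 0.5), 0.0, True, 6.5),
            ((1.0, 1.0, 0.0), 2.0, False, np.exp(-1.0)),
            ((1.0, 1.0, 0.7), 200.0, False, 1e-40),
            ((0.0, None, 0.9), 3.0, False, 0.0),
        ],
    )
    def test_values(self, gamma, d, same, expected):
        g = pg.HyperParams(*gamma)
        assert pg.ou_cov(g, d, same) == pytest.approx(expected, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            pg.ou_cov(pg.HyperParams(1, 1, 0), -0.1)

    def test_cov_matrix_examples(self, two_tip):
        pm = two_tip.patristic_matrix()
        K = pg.cov_matrix(pg.HyperParams(1.0, 1.0, 0.0), pm)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))
        K2 = pg.cov_matrix(pg.HyperParams(2.0, 1.0, 0.5), pm)
        np.testing.assert_allclose(np.diag(K2), 4.25)

    def test_noise_only_on_extant_diagonal(self, three_tip):
        pm = three_tip.patristic_matrix(include_internal=True)
        K = pg.cov_matrix(pg.HyperParams(1.0, 2.0, 0.5), pm)
        diag = np.diag(K)
        assert np.all(diag[pm.is_tip] == pytest.approx(1.25))
        assert np.all(diag[~pm.is_tip] == pytest.approx(1.0))

    def test_psd_over_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = pg.random_tree(int(rng.integers(3, 25)), seed=int(rng.integers(2**31)))
            pm = t.patristic_matrix()
            g = random_gamma(rng, pm.lmax)
            K = pg.cov_matrix(g, pm)
            tol = 1e-8 * np.mean(np.diag(K))
            assert np.linalg.eigvalsh(K).min() >= -tol


class TestLogMarginalLikelihood:
    def test_one_tip_closed_form(self):
        g = pg.HyperParams(1.2, 0.5, 0.4)
        v = g.sigma_f**2 + g.sigma_n**2
        y0 = 0.9
        expected = -0.5 * y0**2 / v - 0.5 * np.log(v) - 0.5 * np.log(2 * np.pi)
        got = pg.log_marginal_likelihood([y0], g, np.zeros((1, 1)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = pg.random_tree(int(rng.integers(3, 10)), seed=int(rng.integers(2**31)))
            pm = t.patristic_matrix()
            g = random_gamma(rng, pm.lmax)
            if g.sigma_n < 0.05:
                g = pg.HyperParams(g.sigma_f, g.ell, 0.3)
            y = rng.normal(size=t.n_tips)
            K = pg.cov_matrix(g, pm)
            oracle = multivariate_normal(np.zeros(t.n_tips), K).logpdf(y)
            assert pg.log_marginal_likelihood(y, g, pm) == pytest.approx(
                oracle, abs=1e-8
            )

    def test_scaling_identity(self):
        rng = np.random.default_rng(2)
        t = pg.random_tree(12, seed=3)
        pm = t.patristic_matrix()
        y = rng.normal(size=12)
        g = pg.HyperParams(1.1, 0.8, 0.6)
        c = 3.7
        gc = pg.HyperParams(c * 1.1, 0.8, c * 0.6)
        lhs = pg.log_marginal_likelihood(c * y, gc, pm)
        rhs = pg.log_marginal_likelihood(y, g, pm) - 12 * np.log(c)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_taxa_reordering_invariance(self):
        rng = np.random.default_rng(3)
        t = pg.random_tree(15, seed=4)
        pm = t.patristic_matrix()
        y = rng.normal(size=15)
        g = pg.HyperParams(1.0, 0.5, 0.3)
        perm = rng.permutation(15)
        base = pg.log_marginal_likelihood(y, g, pm.dist)
        permuted = pg.log_marginal_likelihood(y[perm], g, pm.dist[np.ix_(perm, perm)])
        assert permuted == pytest.approx(base, rel=1e-12)

    def test_independence_limit_small_ell(self):
        """As ell -> 0 tips decorrelate and the likelihood is a sum of 1-D
        Gaussian log-densities with variance sigma_f^2 + sigma_n^2."""
        rng = np.random.default_rng(4)
        t = pg.random_tree(10, seed=5)
        pm = t.patristic_matrix()
        y = rng.normal(size=10)
        g = pg.HyperParams(1.3, 1e-4 * pm.dist[pm.dist > 0].min(), 0.6)
        v = np.sqrt(1.3**2 + 0.6**2)
        assert pg.log_marginal_likelihood(y, g, pm) == pytest.approx(
            norm(0, v).logpdf(y).sum(), rel=1e-9
        )


def _brute_posterior(y, gamma, D, obs, targ):
    """Partitioned-Gaussian conditional via dense inverse (test oracle)."""
    P = gamma.sigma_f**2 * np.exp(-D / (2 * gamma.ell)) if gamma.sigma_f else np.zeros_like(D)
    Kxx = P[np.ix_(obs, obs)] + gamma.sigma_n**2 * np.eye(len(obs))
    Ksx = P[np.ix_(targ, obs)]
    Kss = P[np.ix_(targ, targ)]
    Kinv = np.linalg.inv(Kxx)
    return Ksx @ Kinv @ y, Kss - Ksx @ Kinv @ Ksx.T


class TestGPPosterior:
    def test_noiseless_interpolation_at_tip(self, three_tip):
        pm = three_tip.patristic_matrix(include_internal=True)
        g = pg.HyperParams(1.5, 1.0, 0.0)
        y = np.array([0.3, -1.2, 0.8])
        tip0 = three_tip.tip_ids[0]
        post = gp_posterior(y, g, pm, [tip0], obs_idx=three_tip.tip_ids)
        assert post.mean[0] == pytest.approx(y[0], abs=1e-4)
        assert post.cov[0, 0] == pytest.approx(0.0, abs=1e-4)

    def test_far_target_reverts_to_prior(self):
        t = pg.read_newick("((A:1,B:1):0.5,C:100):0;")
        pm = t.patristic_matrix(include_internal=True)
        g = pg.HyperParams(2.0, 0.5, 0.1)
        obs = [i for i in t.tip_ids if t.labels[i] in ("A", "B")]
        targ = [i for i in t.tip_ids if t.labels[i] == "C"]
        post = gp_posterior(np.array([1.0, -1.0]), g, pm, targ, obs_idx=obs)
        assert post.mean[0] == pytest.approx(0.0, abs=1e-8)
        assert post.cov[0, 0] == pytest.approx(g.sigma_f**2, rel=1e-6)

    def test_matches_brute_force_small_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            t = pg.random_tree(int(rng.integers(3, 7)), seed=int(rng.integers(2**31)))
            pm = t.patristic_matrix(include_internal=True)
            g = random_gamma(rng, max(pm.lmax, 0.1))
            y = rng.normal(size=t.n_tips)
            targ = t.internal_ids
            post = gp_posterior(y, g, pm, targ, obs_idx=t.tip_ids)
            if g.sigma_n < 0.05:
                g = pg.HyperParams(g.sigma_f, g.ell, 0.2)
                post = gp_posterior(y, g, pm, targ, obs_idx=t.tip_ids)
            mu, cov = _brute_posterior(y, g, pm.dist, t.tip_ids, targ)
            np.testing.assert_allclose(post.mean, mu, atol=1e-8)
            np.testing.assert_allclose(post.cov, cov, atol=1e-8)

    def test_posterior_variance_not_above_prior(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = pg.random_tree(int(rng.integers(4, 15)), seed=int(rng.integers(2**31)))
            pm = t.patristic_matrix(include_internal=True)
            g = random_gamma(rng, pm.lmax)
            y = rng.normal(size=t.n_tips)
            post = gp_posterior(y, g, pm, t.internal_ids, obs_idx=t.tip_ids)
            assert np.all(np.diag(post.cov) <= g.sigma_f**2 + 1e-8)
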