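"""Hyperparameter MLE, the known-ratio variant, bagging, robustness study."""

import numpy as np
import pytest
from scipy import stats

import phylogp as pg


def _simulate_y(tree, gamma, seed):
    ss = np.random.SeedSequence(seed).spawn(2)
    y = pg.simulate_ou_on_tree(tree, gamma, np.random.default_rng(ss[0]))[tree.tip_ids]
    return pg.add_tip_noise(y, gamma.sigma_n, np.random.default_rng(ss[1]))


class TestMLEGamma:
    def test_recovers_iid_noise_in_independence_limit(self):
        """Pure-noise data on a tree: sigma_n recovered within 10% and
        sigma_f driven small."""
        t = pg.random_tree(256, seed=0)
        y = np.random.default_rng(1).standard_normal(256)
        g = pg.mle_gamma(y, t.patristic_matrix(), n_restarts=5, seed=0)
        assert g.sigma_n == pytest.approx(1.0, rel=0.10)
        assert g.sigma_f < 0.3

    def test_zero_vector_hits_lower_bounds_flagged(self):
        t = pg.random_tree(16, seed=1)
        g, det = pg.mle_gamma(
            np.zeros(16), t.patristic_matrix(), n_restarts=3, seed=0,
            return_details=True,
        )
        assert det["degenerate_data"]
        assert det["at_lower_bound"][0] and det["at_lower_bound"][2]

    def test_mle_beats_truth_on_sample(self):
        t = pg.random_tree(64, seed=2, scale_lmax=8.22)
        g_true = pg.HyperParams(2.5, 6.17, 0.5)
        y = _simulate_y(t, g_true, 3)
        pm = t.patristic_matrix()
        g_hat = pg.mle_gamma(y, pm, n_restarts=6, seed=0)
        assert pg.log_marginal_likelihood(y, g_hat, pm) >= pg.log_marginal_likelihood(
            y, g_true, pm
        )

    def test_too_short_input(self):
        with pytest.raises(ValueError):
            pg.mle_gamma(np.ones(2), np.zeros((2, 2)))


class TestKnownRatio:
    def test_ratio_zero_pure_noise_closed_form(self):
        t = pg.random_tree(32, seed=3)
        y = np.random.default_rng(0).normal(scale=1.3, size=32)
        g, det = pg.mle_gamma_known_ratio(
            y, t.patristic_matrix(), ratio=0.0, return_details=True
        )
        assert g.sigma_f == 0.0 and g.ell is None
        assert g.sigma_n == pytest.approx(np.sqrt(np.mean(y**2)))
        assert det["ell_unidentifiable"]

    def test_ratio_inf_noise_free(self):
        t = pg.random_tree(32, seed=4, scale_lmax=8.22)
        g_true = pg.HyperParams(1.5, 2.0, 0.0)
        y = _simulate_y(t, g_true, 5)
        g = pg.mle_gamma_known_ratio(
            y, t.patristic_matrix(), ratio=np.inf, n_restarts=5, seed=0
        )
        assert g.sigma_n == 0.0
        assert g.sigma_f > 0

    def test_known_ratio_reduces_sigma_f_spread(self):
        """Constraining sigma_f^2/sigma_n^2 to truth shrinks the spread of
        sigma_f estimates across replicates."""
        free, constrained = [], []
        ratio = 2.5**2 / 0.5**2
        for rep in range(15):
            t = pg.random_tree(64, seed=600 + rep, scale_lmax=8.22)
            g_true = pg.HyperParams(2.5, 0.75 * t.lmax, 0.5)
            y = _simulate_y(t, g_true, 700 + rep)
            pm = t.patristic_matrix()
            free.append(pg.mle_gamma(y, pm, n_restarts=4, seed=rep).sigma_f)
            constrained.append(
                pg.mle_gamma_known_ratio(y, pm, ratio, n_restarts=4, seed=rep).sigma_f
            )
        assert np.std(constrained) <= np.std(free)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            pg.mle_gamma_known_ratio(np.ones(5), np.zeros((5, 5)), ratio=-1.0)


class TestBaggedMLE:
    def test_full_bags_have_zero_spread(self):
        t = pg.random_tree(24, seed=5, scale_lmax=8.22)
        y = _simulate_y(t, pg.HyperParams(1.5, 2.0, 0.5), 6)
        est = pg.bagged_mle(y, tree=t, n_bags=5, bag_size=24, n_restarts=3, seed=0)
        assert est.gamma_sd.sigma_f == 0.0
        assert est.gamma_sd.ell == 0.0

    def test_aggregate_is_mean_of_bags(self):
        t = pg.random_tree(32, seed=6, scale_lmax=8.22)
        y = _simulate_y(t, pg.HyperParams(1.5, 2.0, 0.5), 7)
        est = pg.bagged_mle(y, tree=t, n_bags=8, bag_size=24, n_restarts=3, seed=1)
        assert est.gamma_hat.sigma_f == pytest.approx(est.per_bag["sigma_f"].mean())
        assert est.gamma_hat.ell == pytest.approx(est.per_bag["ell"].mean())
        assert est.gamma_sd.sigma_n == pytest.approx(
            est.per_bag["sigma_n"].std(ddof=1)
        )
        assert est.n_bags == len(est.per_bag)

    def test_pure_noise_raises_small_ell_diagnostic(self):
        t = pg.random_tree(64, seed=7, scale_lmax=8.22)
        y = np.random.default_rng(8).standard_normal(64)
        est = pg.bagged_mle(y, tree=t, n_bags=15, n_restarts=4, seed=2)
        assert est.diagnostics["signal_absent_small_ell"]
        q1, q99 = est.diagnostics["ell_percentiles"]
        assert est.gamma_hat.ell < q1 < q99

    def test_bagging_not_more_variable_than_single_mle(self):
        """One-sided F comparison at the 10% level: across replicates the
        bagged sigma_f estimator is not significantly more variable than
        the full-tree MLE."""
        bagged, single = [], []
        for rep in range(12):
            t = pg.random_tree(48, seed=900 + rep, scale_lmax=8.22)
            g_true = pg.HyperParams(2.5, 0.75 * t.lmax, 0.5)
            y = _simulate_y(t, g_true, 950 + rep)
            est = pg.bagged_mle(y, tree=t, n_bags=12, bag_size=38, n_restarts=3,
                                seed=rep)
            bagged.append(est.gamma_hat.sigma_f)
            single.append(
                pg.mle_gamma(y, t.patristic_matrix(), n_restarts=5, seed=rep).sigma_f
            )
        F = np.var(bagged, ddof=1) / np.var(single, ddof=1)
        assert F <= stats.f.ppf(0.90, len(bagged) - 1, len(single) - 1)

    def test_estimation_improves_with_tree_size(self):
        """Mean |sigma_f error| decreases as taxa accumulate (32 -> 64 -> 128),
        with the tree extent growing naturally with n."""
        errs = {}
        for n in (32, 64, 128):
            e = []
            for rep in range(12):
                t = pg.random_tree(n, seed=3000 + rep)
                g_true = pg.HyperParams(1.5, 1.0, 0.5)
                y = _simulate_y(t, g_true, 4000 + 100 * n + rep)
                gh = pg.mle_gamma(y, t.patristic_matrix(), n_restarts=5, seed=rep)
                e.append(abs(gh.sigma_f - 1.5))
            errs[n] = np.mean(e)
        assert errs[32] >= errs[64] >= errs[128]

    def test_bag_size_bounds(self):
        t = pg.random_tree(16, seed=9)
        with pytest.raises(ValueError):
            pg.bagged_mle(np.ones(16), tree=t, n_bags=2, bag_size=17)


class TestBaggedOUEstimatorAPI:
    def test_sklearn_params_and_fit(self):
        est = pg.BaggedOUEstimator(n_bags=6, bag_size=20, n_restarts=3, random_state=0)
        assert est.get_params()["n_bags"] == 6
        t = pg.random_tree(24, seed=10, scale_lmax=8.22)
        y = _simulate_y(t, pg.HyperParams(1.5, 2.0, 0.5), 11)
        est.fit(y, tree=t)
        assert isinstance(est.gamma_, pg.HyperParams)
        assert len(est.per_bag_) == 6
        assert np.isfinite(est.score(y, tree=t))


class TestRobustnessStudy:
    def test_zero_runs_empty(self):
        df, med = pg.robustness_study(0, seed=0)
        assert df.empty and med == {}

    def test_fixed_sigma_n_has_zero_error(self):
        df, med = pg.robustness_study(
            6, n_tips=24, seed=1, n_restarts=3, fix={"sigma_n": True}
        )
        assert med["sigma_n"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(df["rel_err_sigma_n"], 0.0, atol=1e-12)

    def test_table_columns_and_finite(self):
        df, med = pg.robustness_study(5, n_tips=24, seed=2, n_restarts=3)
        ok = df[~df["failed"]]
        assert {"rel_err_sigma_f", "rel_err_ell", "rel_err_sigma_n"} <= set(df.columns)
        assert np.isfinite(ok["rel_err_sigma_f"]).all()
        assert set(med) == {"sigma_f", "ell", "sigma_n"}
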