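import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.cross_decomposition import CCA as SklearnCCA

from bwasim.multivariate import (MultivariateConfig, cca_train_eval,
                                 first_canonical_pair,
                                 multivariate_learning_curve,
                                 permutation_threshold, svr_train_eval)
from bwasim.synthpop import SplitAssignment, split_discovery_replication


def _split(n):
    ids = np.arange(n)
    return SplitAssignment(discovery_ids=ids[: n // 2], replication_ids=ids[n // 2:])


class TestFirstCanonicalPair:
    def test_matches_brute_force_optimizer(self):
        rng = np.random.default_rng(0)
        n = 200
        A = rng.standard_normal((n, 4))
        B = 0.5 * A[:, :3] + rng.standard_normal((n, 3))
        rho, a, b = first_canonical_pair(A, B)

        Ac, Bc = A - A.mean(0), B - B.mean(0)

        def neg_corr(v):
            x = Ac @ v[:4]
            y = Bc @ v[4:]
            return -np.corrcoef(x, y)[0, 1]

        best = min(
            (minimize(neg_corr, rng.standard_normal(7), method="Nelder-Mead",
                      options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
             for _ in range(4)),
            key=lambda res: res.fun,
        )
        assert rho == pytest.approx(-best.fun, abs=1e-4)

    def test_matches_sklearn_cca(self):
        rng = np.random.default_rng(1)
        n = 300
        A = rng.standard_normal((n, 5))
        B = 0.4 * A[:, :2] + rng.standard_normal((n, 4))[:, :2] @ np.ones((2, 2)) * 0.1
        B = np.column_stack([B, rng.standard_normal(n)])
        rho, a, b = first_canonical_pair(A, B)
        skl = SklearnCCA(n_components=1, max_iter=2000).fit(A, B)
        xs, ys = skl.transform(A, B)
        rho_skl = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
        assert rho == pytest.approx(rho_skl, abs=1e-3)

    def test_rank_deficient_battery_rejected(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((50, 3))
        B = np.tile(rng.standard_normal((50, 1)), (1, 2))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            first_canonical_pair(A, B)


class TestCcaTrainEval:
    def test_perfect_shared_factor(self):
        # Single latent factor, (nearly) noise-free indicators on both sides.
        rng = np.random.default_rng(3)
        n = 400
        g = rng.standard_normal(n)
        X = np.outer(g, rng.uniform(0.5, 1.5, 5)) + 1e-3 * rng.standard_normal((n, 5))
        Y = np.outer(g, rng.uniform(0.5, 1.5, 3)) + 1e-3 * rng.standard_normal((n, 3))
        cfg = MultivariateConfig(method="cca", pca_variance_threshold=1.0)
        in_r, out_r, _ = cca_train_eval(X[:200], Y[:200], X[200:], Y[200:], cfg)
        assert in_r > 0.999
        assert out_r > 0.999

    def test_permuted_battery_null(self):
        rng = np.random.default_rng(4)
        n = 600
        X = rng.standard_normal((n, 40))
        Y = rng.standard_normal((n, 5))
        outs = []
        for i in range(20):
            perm = rng.permutation(n // 2)
            _, out_r, _ = cca_train_eval(
                X[: n // 2], Y[: n // 2][perm], X[n // 2:], Y[n // 2:],
                MultivariateConfig(method="cca"),
            )
            outs.append(out_r)
        assert abs(np.mean(outs)) < 0.05

    def test_battery_needs_two_variables(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            cca_train_eval(rng.standard_normal((50, 4)),
                           rng.standard_normal((50, 1)),
                           rng.standard_normal((50, 4)),
                           rng.standard_normal((50, 1)))


class TestSvrTrainEval:
    def test_permuted_phenotype_gives_null_prediction(self, strong_pop):
        # The permutation-null r_pred distribution is centred at zero (it is
        # wider than the 1/sqrt(n) independence band because a noise-fit
        # model can still load on the dominant brain component).
        split = split_discovery_replication(strong_pop, seed=1)
        X, y = strong_pop.features, strong_pop.phenotype()
        rng = np.random.default_rng(6)
        Xd, yd = X[split.discovery_ids], y[split.discovery_ids]
        Xr, yr = X[split.replication_ids], y[split.replication_ids]
        nulls = np.array([
            svr_train_eval(Xd, rng.permutation(yd), Xr, yr)[1]
            for _ in range(12)
        ])
        assert abs(nulls.mean()) < 3 * nulls.std(ddof=1) / np.sqrt(12) + 0.02
        # The unpermuted model beats every permuted one.
        _, r_pred, _ = svr_train_eval(Xd, yd, Xr, yr)
        assert r_pred > nulls.max()

    def test_signal_recovered_out_of_sample(self, strong_pop):
        split = split_discovery_replication(strong_pop, seed=1)
        X, y = strong_pop.features, strong_pop.phenotype()
        in_r, r_pred, info = svr_train_eval(
            X[split.discovery_ids], y[split.discovery_ids],
            X[split.replication_ids], y[split.replication_ids],
        )
        assert r_pred > 0.3
        assert in_r > r_pred  # in-sample optimism

    def test_no_leakage_from_replication_half(self, strong_pop):
        # Perturbing replication rows leaves the trained model bit-identical.
        split = split_discovery_replication(strong_pop, seed=1)
        X, y = strong_pop.features, strong_pop.phenotype()
        Xd, yd = X[split.discovery_ids], y[split.discovery_ids]
        Xr, yr = X[split.replication_ids], y[split.replication_ids]
        rng = np.random.default_rng(7)
        Xr2 = Xr + rng.standard_normal(Xr.shape)
        probe = rng.standard_normal((5, X.shape[1]))
        _, _, info1 = svr_train_eval(Xd, yd, Xr, yr)
        _, _, info2 = svr_train_eval(Xd, yd, Xr2, yr)
        np.testing.assert_array_equal(info1["model"].coef_, info2["model"].coef_)
        np.testing.assert_array_equal(
            info1["model"].predict(info1["project"](probe)),
            info2["model"].predict(info2["project"](probe)),
        )


class TestLearningCurve:
    def test_overfitting_direction_and_variability_shrinks(self, strong_pop):
        split = split_discovery_replication(strong_pop, seed=2)
        cfg = MultivariateConfig(method="svr", bins=(25, 100, 400),
                                 n_bootstrap=12, seed=3)
        res = multivariate_learning_curve(
            strong_pop.features, strong_pop.phenotype(), split, cfg)
        s = res.summary().set_index("bin")
        assert (s.mean_in_r > s.mean_out_r).all()
        assert s.sd_out_r.loc[400] < s.sd_out_r.loc[25]
        assert s.mean_out_r.loc[400] > s.mean_out_r.loc[25]

    def test_deterministic_given_seed(self, strong_pop):
        split = split_discovery_replication(strong_pop, seed=2)
        cfg = MultivariateConfig(method="svr", bins=(50,), n_bootstrap=4, seed=5)
        a = multivariate_learning_curve(strong_pop.features,
                                        strong_pop.phenotype(), split, cfg)
        b = multivariate_learning_curve(strong_pop.features,
                                        strong_pop.phenotype(), split, cfg)
        assert a.table.equals(b.table)

    def test_bin_exceeding_discovery_rejected(self, strong_pop):
        split = split_discovery_replication(strong_pop, seed=2)
        cfg = MultivariateConfig(bins=(5000,), n_bootstrap=2)
        with pytest.raises(ValueError):
            multivariate_learning_curve(strong_pop.features,
                                        strong_pop.phenotype(), split, cfg)


class TestPermutationThreshold:
    def test_cutoff_calibration_and_determinism(self, strong_pop):
        split = split_discovery_replication(strong_pop, seed=2)
        X, y = strong_pop.features, strong_pop.phenotype()
        Xd, yd = X[split.discovery_ids], y[split.discovery_ids]
        Xr, yr = X[split.replication_ids], y[split.replication_ids]
        cfg = MultivariateConfig(method="svr", n_permutations=100, seed=9)
        cut1, null1 = permutation_threshold(Xd, yd, Xr, yr, cfg, quantile=0.99)
        cut2, _ = permutation_threshold(Xd, yd, Xr, yr, cfg, quantile=0.99)
        assert cut1 == cut2
        # Null distribution is centred at zero with SD ~ 1/sqrt(n_rep).
        assert abs(np.mean(null1)) < 3.0 / np.sqrt(yr.size)
        # The genuine out-of-sample association clears the null cutoff.
        _, r_pred, _ = svr_train_eval(Xd, yd, Xr, yr)
        assert r_pred > cut1

    def test_quantile_needs_enough_permutations(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        with pytest.raises(ValueError):
            permutation_threshold(X, y, X, y,
                                  MultivariateConfig(n_permutations=100),
                                  quantile=0.9999)
        with pytest.raises(ValueError):
            permutation_threshold(X, y, X, y,
                                  MultivariateConfig(n_permutations=50))


class TestFeatureRanking:
    def test_ranking_variant_runs_and_reports_k(self, strong_pop):
        split = split_discovery_replication(strong_pop, seed=2)
        cfg = MultivariateConfig(method="svr", bins=(100,), n_bootstrap=3,
                                 feature_rank_k=40, seed=4)
        res = multivariate_learning_curve(
            strong_pop.features, strong_pop.phenotype(), split, cfg)
        assert (res.table.n_components == 40).all()
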