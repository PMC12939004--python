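"""PCA/PCR/PLS correctness against independent oracles, MCCV behavior."""

import numpy as np
import pytest

from meatwhc import (DesignMatrix, center, pca_fit, select_k, pcr_fit,
                     pls_nipals_fit, predict, predict_sequential,
                     mccv_select_lv)
from _oracles import simpls_beta, eig_pca_ratios, ols_predict


def random_problem(rng, n, p, noise=0.1):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return DesignMatrix(X=X, y=y)


class TestPCA:
    def test_rank_one_data_single_ratio(self):
        t = np.linspace(-2, 2, 9)
        Xc = np.column_stack([t, 3 * t])
        m = pca_fit(Xc)
        np.testing.assert_allclose(m.explained_ratio, [1.0], atol=1e-12)

    def test_ratios_sum_to_one_over_full_rank(self, rng):
        Xc = rng.normal(size=(8, 5))
        Xc -= Xc.mean(axis=0)
        m = pca_fit(Xc)
        assert m.explained_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(m.explained_ratio) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        Xc = rng.normal(size=(8, 5))
        Xc -= Xc.mean(axis=0)
        m = pca_fit(Xc)
        np.testing.assert_allclose(m.explained_ratio, eig_pca_ratios(Xc)[:m.k],
                                   atol=1e-8)

    def test_loadings_orthonormal_scores_orthogonal(self, rng):
        Xc = rng.normal(size=(10, 6))
        Xc -= Xc.mean(axis=0)
        m = pca_fit(Xc)
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(m.k),
                                   atol=1e-8)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_scores_reproduce_projection(self, rng):
        Xc = rng.normal(size=(7, 4))
        Xc -= Xc.mean(axis=0)
        m = pca_fit(Xc)
        np.testing.assert_allclose(m.scores, Xc @ m.loadings, atol=1e-10)

    def test_k_max_beyond_rank_truncates_with_warning(self):
        t = np.linspace(-1, 1, 6)
        Xc = np.column_stack([t, 2 * t, -t])
        with pytest.warns(UserWarning, match="rank"):
            m = pca_fit(Xc, k_max=3)
        assert m.k == 1


class TestSelectK:
    @pytest.mark.parametrize("cum,threshold,expected", [
        ([0.5, 0.94, 0.951, 0.99], 0.95, 3),
        ([1.0], 0.95, 1),
    ])
    def test_linear_scan(self, cum, threshold, expected):
        assert select_k(np.array(cum), threshold) == expected

    def test_component_count_at_study_scale_threshold(self):
        # a cumulative curve first crossing 0.95 at position 16 with the
        # study's reported terminal contribution of 96.394%
        cum = np.concatenate([np.linspace(0.30, 0.945, 15), [0.96394]])
        assert select_k(cum, 0.95) == 16

    def test_never_reaching_threshold_warns_full_rank(self):
        with pytest.warns(UserWarning, match="full rank"):
            assert select_k(np.array([0.4, 0.6, 0.7]), 0.95) == 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            select_k(np.array([]), 0.95)
        with pytest.raises(ValueError):
            select_k(np.array([0.5, 1.0]), 1.5)


class TestPCR:
    def test_full_rank_equals_ols(self, rng):
        d = random_problem(rng, 12, 5)
        model = pcr_fit(d, k=5)
        np.testing.assert_allclose(predict(model, d.X),
                                   ols_predict(d.X, d.y, d.X), atol=1e-8)

    def test_response_in_pc1_fits_with_one_component(self, rng):
        t = rng.normal(size=20)
        direction = np.array([3.0, 1.0, -2.0])
        X = np.outer(t, direction) + 1e-3 * rng.normal(size=(20, 3))
        y = 2.0 + 5.0 * (X @ direction)
        d = DesignMatrix(X=X, y=y)
        model = pcr_fit(d, k=1)
        assert np.max(np.abs(predict(model, X) - y)) < 1e-6 * np.abs(y).max()

    def test_matches_two_step_oracle(self, rng):
        d = random_problem(rng, 20, 6)
        k = 3
        model = pcr_fit(d, k)
        # independent route: explicit PCA then normal-equations regression
        Xc = d.X - d.X.mean(axis=0)
        yc = d.y - d.y.mean()
        vals, vecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(vals)[::-1][:k]
        L = vecs[:, order]
        T = Xc @ L
        gamma = np.linalg.solve(T.T @ T, T.T @ yc)
        beta = L @ gamma
        # eigenvector signs are arbitrary; compare the invariant beta
        np.testing.assert_allclose(model.beta, beta, atol=1e-8)

    def test_k_exceeding_rank_rejected(self, rng):
        d = random_problem(rng, 4, 6)
        with pytest.raises(ValueError):
            pcr_fit(d, k=5)

    def test_calibration_rmse_nonincreasing_in_k(self, rng):
        from meatwhc import rmse
        d = random_problem(rng, 15, 6, noise=1.0)
        errs = [rmse(d.y, predict(pcr_fit(d, k), d.X)) for k in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestPLS:
    def test_single_feature_collapses_to_simple_regression(self, rng):
        x = rng.normal(size=30)
        y = 2.0 + 3.0 * x + 0.1 * rng.normal(size=30)
        d = DesignMatrix(X=x[:, None], y=y)
        model = pls_nipals_fit(d, A=1)
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert model.beta[0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_equals_ols(self, rng):
        d = random_problem(rng, 12, 5)
        model = pls_nipals_fit(d, A=5)
        np.testing.assert_allclose(predict(model, d.X),
                                   ols_predict(d.X, d.y, d.X), atol=1e-8)

    def test_matches_simpls_oracle(self, rng):
        d = random_problem(rng, 25, 10, noise=0.5)
        model = pls_nipals_fit(d, A=4)
        beta, intercept = simpls_beta(d.X, d.y, 4)
        np.testing.assert_allclose(model.beta, beta, atol=1e-6)
        assert model.intercept == pytest.approx(intercept, abs=1e-6)

    def test_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        d = random_problem(rng, 25, 8, noise=0.5)
        model = pls_nipals_fit(d, A=3)
        sk = PLSRegression(n_components=3, scale=False).fit(d.X, d.y)
        np.testing.assert_allclose(model.beta, sk.coef_.ravel(), atol=1e-6)

    def test_score_orthogonality(self, rng):
        d = random_problem(rng, 20, 12, noise=1.0)
        model = pls_nipals_fit(d, A=6)
        T = model.T
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(T[:, i] @ T[:, j]) < 1e-8 * \
                    np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])

    def test_constant_response_rejected(self, rng):
        d = DesignMatrix(X=rng.normal(size=(6, 3)), y=np.full(6, 7.0))
        with pytest.raises(ValueError):
            pls_nipals_fit(d, A=1)

    def test_excess_components_truncated_with_warning(self, rng):
        d = random_problem(rng, 5, 3, noise=0.0)
        with pytest.warns(UserWarning, match="truncated"):
            model = pls_nipals_fit(d, A=10)
        assert model.A < 10

    def test_calibration_rmse_nonincreasing_in_A(self, rng):
        from meatwhc import rmse
        d = random_problem(rng, 15, 6, noise=1.0)
        errs = [rmse(d.y, predict(pls_nipals_fit(d, a), d.X))
                for a in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestPredict:
    def test_column_means_row_predicts_response_mean(self, rng):
        d = random_problem(rng, 15, 6)
        model = pls_nipals_fit(d, A=3)
        pred = predict(model, d.X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(d.y.mean(), abs=1e-10)

    def test_beta_path_equals_sequential_path(self, rng):
        d = random_problem(rng, 18, 7, noise=0.5)
        model = pls_nipals_fit(d, A=4)
        X_new = rng.normal(size=(5, 7))
        np.testing.assert_allclose(predict(model, X_new),
                                   predict_sequential(model, X_new), atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        d = random_problem(rng, 10, 4)
        model = pls_nipals_fit(d, A=2)
        with pytest.raises(ValueError):
            predict(model, np.ones((2, 5)))

    def test_triple_equivalence_at_full_rank(self, rng):
        d = random_problem(rng, 14, 6)
        ols = ols_predict(d.X, d.y, d.X)
        np.testing.assert_allclose(predict(pcr_fit(d, 6), d.X), ols, atol=1e-8)
        np.testing.assert_allclose(predict(pls_nipals_fit(d, 6), d.X), ols,
                                   atol=1e-8)


class TestMCCV:
    def test_exact_one_dimensional_signal_selects_one(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=8))
        X += 1e-8 * rng.normal(size=X.shape)
        y = 1.0 + 2.0 * t
        d = DesignMatrix(X=X, y=y)
        res = mccv_select_lv(d, A_max=5, n_splits=30, seed=0)
        assert res.chosen_A == 1

    def test_bit_identical_reruns(self, rng):
        d = random_problem(rng, 20, 6, noise=1.0)
        a = mccv_select_lv(d, A_max=4, n_splits=25, seed=3)
        b = mccv_select_lv(d, A_max=4, n_splits=25, seed=3)
        np.testing.assert_array_equal(a.rmse_curve, b.rmse_curve)
        assert a.chosen_A == b.chosen_A

    def test_recovers_rank_three_signal(self):
        # three orthogonal latent directions, 5% noise: the chosen order
        # should sit at 3 +/- 1 in at least 95% of 50 master seeds
        hits = 0
        n, p = 60, 40
        for master in range(50):
            rng = np.random.default_rng(1000 + master)
            T = rng.normal(size=(n, 3))
            D = np.linalg.qr(rng.normal(size=(p, 3)))[0]
            X = T @ D.T
            c = np.array([3.0, -2.0, 1.0])
            y = T @ c
            sig = np.std(y)
            X += 0.05 * rng.normal(size=X.shape)
            y = y + 0.05 * sig * rng.normal(size=n)
            res = mccv_select_lv(DesignMatrix(X=X, y=y), A_max=5,
                                 n_splits=200, seed=master)
            hits += res.chosen_A in (2, 3, 4)
        assert hits >= 48

    def test_chosen_is_argmin_with_smallest_tie(self, rng):
        d = random_problem(rng, 20, 6, noise=1.0)
        res = mccv_select_lv(d, A_max=4, n_splits=20, seed=5)
        assert res.chosen_A == int(np.argmin(res.rmse_curve)) + 1
        assert 1 <= res.chosen_A <= 4
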