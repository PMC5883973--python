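import numpy as np
import pytest

from calfnmr.chemometrics import fit_opls, glog, mccv, pca, predict_opls


# ---------------------------------------------------------------------------
# independent oracles

def nipals_pls2(X, Y, n_components, tol=1e-14, max_iter=10_000):
    """Textbook NIPALS PLS2 with X and Y deflation (test oracle)."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    Xd, Yd = X.copy(), Y.copy()
    W, P, Q = [], [], []
    for _ in range(n_components):
        u = Yd[:, np.argmax(Yd.var(axis=0))].copy()
        w = np.zeros(X.shape[1])
        for _ in range(max_iter):
            w_new = Xd.T @ u
            w_new /= np.linalg.norm(w_new)
            t = Xd @ w_new
            q = Yd.T @ t / (t @ t)
            u_new = Yd @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = Yd.T @ t / (t @ t)
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, q)
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = map(np.column_stack, (W, P, Q))
    return W @ np.linalg.solve(P.T @ W, Q.T)


def dummy(labels, classes):
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(labels) == c, j] = 1.0
    return Y


# ---------------------------------------------------------------------------
# PCA

class TestPCA:
    def test_points_on_line_explained_by_one_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([2 * t, -3 * t])
        res = pca(X, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5))
        res = pca(X, 5)
        rec = res.scores @ res.loadings.T + res.mean
        assert np.allclose(rec, X, atol=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        res = pca(X, 3)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.allclose(res.explained_variance, eigvals[:3], atol=1e-8)

    def test_loadings_orthonormal_scores_uncorrelated(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 7))
        res = pca(X, 5)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)
        cov = np.cov(res.scores.T)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-10)
        assert (np.diff(res.explained_variance) <= 1e-12).all()

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca(np.eye(3), 3)


# ---------------------------------------------------------------------------
# OPLS

class TestOPLS:
    @pytest.mark.parametrize("shape,k,n_pred", [((20, 12), 2, 3), ((15, 30), 3, 2),
                                                ((40, 8), 4, 3)])
    def test_zero_orthogonal_equals_pls2_oracle(self, shape, k, n_pred):
        rng = np.random.default_rng(7)
        X = rng.normal(size=shape)
        labels = np.array([f"c{i % k}" for i in range(shape[0])])
        classes = sorted(set(labels))
        model = fit_opls(X, labels, n_pred=n_pred, n_orth=0)
        _, mine = predict_opls(model, X)

        Y = dummy(labels, classes)
        B = nipals_pls2(X, Y, n_pred)
        oracle = (X - X.mean(0)) @ B + Y.mean(0)
        assert np.allclose(mine, oracle, atol=1e-8)

    def test_pls_predictions_cross_checked_against_sklearn(self):
        # independent-library sanity check; tolerance reflects sklearn's
        # looser NIPALS convergence threshold, not our own contract
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(19)
        X = rng.normal(size=(30, 12))
        labels = np.array([f"c{i % 3}" for i in range(30)])
        classes = sorted(set(labels))
        Y = dummy(labels, classes)
        model = fit_opls(X, labels, n_pred=4, n_orth=0)
        _, mine = predict_opls(model, X)
        skl = PLSRegression(n_components=4, scale=False, tol=1e-10,
                            max_iter=5000).fit(X, Y).predict(X)
        assert np.abs(mine - skl).max() < 1e-4

    def test_orthogonal_scores_uncorrelated_with_response(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 30))
        labels = np.array(["a", "b"] * 10)
        model = fit_opls(X, labels, n_pred=1, n_orth=3)
        Y = dummy(labels, model.classes)
        Yc = Y - Y.mean(0)
        for kcol in range(Yc.shape[1]):
            for j in range(model.n_orth):
                cov = model.orth_scores[:, j] @ Yc[:, kcol]
                assert abs(cov) < 1e-8 * np.linalg.norm(model.orth_scores[:, j])

    def test_predictive_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 10))
        labels = np.array(["a", "b", "c", "d", "e"] * 5)
        model = fit_opls(X, labels, n_pred=4, n_orth=2)
        G = model.pred_scores.T @ model.pred_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (10, 4)), rng.normal(5, 0.1, (10, 4))])
        labels = np.array(["lo"] * 10 + ["hi"] * 10)
        model = fit_opls(X, labels, n_pred=1, n_orth=0)
        pred, _ = predict_opls(model, X)
        assert list(pred) == list(labels)

    def test_class_mean_row_predicted_as_that_class(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.1, (8, 5)), rng.normal(4, 0.1, (8, 5))])
        labels = np.array(["a"] * 8 + ["b"] * 8)
        model = fit_opls(X, labels, n_pred=1, n_orth=1)
        pred, _ = predict_opls(model, X[8:].mean(0))
        assert pred == ["b"]

    def test_tie_breaks_to_first_class_in_order(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        labels = ["a", "a", "b", "b"]  # X carries no class information
        model = fit_opls(np.hstack([X, np.array([[1.0], [-1], [-1], [1]])]),
                         labels, n_pred=1, n_orth=0)
        # exact tie: a row at the training center scores y_mean for each class
        pred, scores = predict_opls(model, model.center_vector)
        assert np.allclose(scores[0], scores[0][0])
        assert pred == ["a"]

    def test_constant_matrix_rejected(self):
        X = np.ones((8, 4))
        with pytest.raises(ValueError, match="constant"):
            fit_opls(X, ["a", "b"] * 4, n_pred=1, n_orth=0)

    def test_small_class_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_opls(X, ["a", "a", "a", "a", "b"], n_pred=1, n_orth=0)

    def test_bin_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 4))
        model = fit_opls(X, ["a", "b"] * 5, n_pred=1, n_orth=0)
        with pytest.raises(ValueError, match="bin mismatch"):
            predict_opls(model, np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# MCCV

class TestMCCV:
    def test_chance_level_on_structureless_data(self):
        # 7 balanced classes, pure noise: accuracy must sit at 1/7 within
        # 3 binomial standard errors of the total test-prediction count
        rng = np.random.default_rng(11)
        n_per, k = 20, 7
        X = rng.normal(size=(n_per * k, 25))
        labels = np.repeat([f"g{i}" for i in range(k)], n_per)
        rep = mccv(X, labels, n_iterations=100, n_pred=6, n_orth=4, seed=0)
        total = rep.confusion.sum()
        se = np.sqrt((1 / k) * (1 - 1 / k) / total)
        assert abs(rep.mean_accuracy - 1 / k) <= 3 * se

    def test_duplicated_rows_give_perfect_accuracy(self):
        a = np.tile([1.0, 0.0, 2.0], (10, 1))
        b = np.tile([0.0, 3.0, 1.0], (10, 1))
        X = np.vstack([a, b]) + np.random.default_rng(1).normal(0, 1e-9, (20, 3))
        labels = ["a"] * 10 + ["b"] * 10
        rep = mccv(X, labels, n_iterations=20, n_pred=1, n_orth=0, seed=2)
        assert rep.mean_accuracy == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 6))
        labels = ["a", "b", "c", "d"] * 10
        r1 = mccv(X, labels, n_iterations=10, n_pred=2, n_orth=1, seed=5)
        r2 = mccv(X, labels, n_iterations=10, n_pred=2, n_orth=1, seed=5)
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_confusion_row_sums_count_test_appearances(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 5))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        rep = mccv(X, labels, n_iterations=25, n_pred=2, n_orth=0, seed=1)
        assert rep.confusion.sum(axis=1).tolist() == [25, 25, 25]
        assert np.all(rep.per_class_sensitivity >= 0)
        assert np.all(rep.per_class_sensitivity <= 1)
        assert np.all(rep.per_class_specificity <= 1)

    def test_train_fraction_leaving_class_empty_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="train"):
            mccv(X, ["a", "a", "b", "b", "b", "b"], train_fraction=0.5,
                 n_pred=1, n_orth=0)

    def test_report_formatting_includes_confusion(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 4))
        rep = mccv(X, ["a", "b"] * 10, n_iterations=5, n_pred=1, n_orth=0, seed=0)
        text = rep.format()
        assert "confusion matrix" in text
        assert "mean accuracy" in text


class TestGlog:
    def test_behaves_like_log_for_large_values(self):
        x = np.array([1.0, 10.0, 100.0])
        assert np.allclose(glog(x, 1e-12), np.log(x), atol=1e-10)

    def test_defined_and_monotone_for_negatives(self):
        x = np.linspace(-0.01, 0.01, 101)
        y = glog(x, 1e-6)
        assert np.all(np.isfinite(y))
        assert np.all(np.diff(y) > 0)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            glog(np.ones(3), 0.0)
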