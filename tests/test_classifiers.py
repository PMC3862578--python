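import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from wrapsel.classifiers import (
    fit_lda,
    fit_lda_arrays,
    fit_linear_svm_arrays,
    fit_nsc_arrays,
    svm_weight_magnitudes,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def gaussian_posterior_oracle(model, X):
    """Class posteriors by direct equal-covariance density evaluation
    (log densities, so far-out queries do not underflow)."""
    S = model.pooled_cov + model.ridge * np.eye(model.n_features)
    logd = np.column_stack([
        multivariate_normal.logpdf(X, mean=model.means[k], cov=S)
        + np.log(model.priors[k])
        for k in (0, 1)
    ])
    logd -= logd.max(axis=1, keepdims=True)
    dens = np.exp(logd)
    return dens / dens.sum(axis=1, keepdims=True)


def generic_qp_svm_oracle(X, y, C):
    """Generic QP solve of the soft-margin dual via SLSQP; by strong duality
    the returned value equals the optimal primal objective."""
    n = X.shape[0]
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def objective(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = minimize(
        objective, np.full(n, min(C, 1.0) / 2), jac=jac, constraints=cons,
        bounds=[(0, C)] * n, method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return -res.fun


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

class TestLDA:
    def test_1d_toy_pooled_variance_and_boundary(self, toy_1d):
        model = fit_lda(toy_1d)
        np.testing.assert_allclose(model.means.ravel(), [1.0, 5.0])
        np.testing.assert_allclose(model.pooled_cov, [[2.0]])
        np.testing.assert_allclose(model.priors, [0.5, 0.5])
        # equal priors and variance -> boundary at the midpoint x = 3
        assert model.predict([[2.9]]) == [0]
        assert model.predict([[3.1]]) == [1]
        w, c = model.linear_boundary()
        np.testing.assert_allclose(-c / w[0], 3.0)

    def test_posteriors_match_density_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(14, 3)) @ rng.normal(size=(3, 3)) + rng.normal(
                size=3
            )
            y = np.array([0] * 6 + [1] * 8)
            model = fit_lda_arrays(X, y)
            Xq = rng.normal(size=(10, 3))
            np.testing.assert_allclose(
                model.posterior(Xq), gaussian_posterior_oracle(model, Xq),
                atol=1e-10,
            )

    def test_two_class_sign_matches_closed_form(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 5 + [1] * 7)
        model = fit_lda_arrays(X, y)
        g = model.discriminants(X)
        w = np.linalg.solve(model.pooled_cov, model.means[1] - model.means[0])
        c = -0.5 * (model.means[1] + model.means[0]) @ w + np.log(7 / 5)
        np.testing.assert_allclose(g[:, 1] - g[:, 0], X @ w + c, atol=1e-10)

    def test_translation_invariance(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 5 + [1] * 5)
        shift = np.array([100.0, -40.0])
        pred1 = fit_lda_arrays(X, y).predict(X)
        pred2 = fit_lda_arrays(X + shift, y).predict(X + shift)
        np.testing.assert_array_equal(pred1, pred2)

    def test_boundary_tie_goes_positive(self):
        X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_lda_arrays(X, y)
        assert model.predict([[0.0]]) == [1]

    def test_identical_distributions_decided_by_priors(self):
        # same points in both classes, unbalanced priors -> majority wins
        X = np.vstack([np.array([[0.0], [1.0]])] * 3)
        y = np.array([0, 0, 0, 0, 1, 1])
        model = fit_lda_arrays(X, y)
        np.testing.assert_array_equal(model.predict([[0.0], [1.0]]), [0, 0])

    def test_error_conditions(self, rng):
        with pytest.raises(ValueError):
            fit_lda_arrays(rng.normal(size=(4, 2)), np.array([0, 1, 1, 1]))
        model = fit_lda_arrays(rng.normal(size=(6, 2)), np.array([0, 0, 0, 1, 1, 1]))
        with pytest.raises(ValueError, match="features"):
            model.predict([[1.0, 2.0, 3.0]])

    def test_singular_covariance_gets_ridge(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 3.0], [4.0, 4.0]])
        y = np.array([0, 0, 1, 1])  # duplicated feature -> singular pooled cov
        model = fit_lda_arrays(X, y)
        assert model.ridge > 0
        np.testing.assert_array_equal(model.predict(X), y)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

class TestLinearSVM:
    def test_symmetric_pair(self):
        model = fit_linear_svm_arrays(
            np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=10.0
        )
        np.testing.assert_allclose(model.weights, [1.0], atol=1e-8)
        assert abs(model.bias) < 1e-8
        np.testing.assert_allclose(model.margin, 2.0, atol=1e-8)

    def test_duplicating_samples_leaves_solution_unchanged(self, rng):
        # holds when no slack is active: the duplicated points' penalty term
        # is zero, so only the dual coefficients rescale
        X = np.vstack([rng.normal(size=(4, 2)) - 3, rng.normal(size=(4, 2)) + 3])
        y = np.array([-1.0] * 4 + [1.0] * 4)
        m1 = fit_linear_svm_arrays(X, y, C=1.0)
        m2 = fit_linear_svm_arrays(np.vstack([X, X]), np.tile(y, 2), C=1.0)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-6)
        assert abs(m1.bias - m2.bias) < 1e-6

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_matches_generic_qp_solve(self, rng, C):
        for _ in range(3):
            X = np.vstack([
                rng.normal(size=(6, 2)) + [2.5, 0.0],
                rng.normal(size=(6, 2)) - [2.5, 0.0],
            ])
            y = np.array([1.0] * 6 + [-1.0] * 6)
            model = fit_linear_svm_arrays(X, y, C=C)
            oracle_obj = generic_qp_svm_oracle(X, y, C)
            assert abs(model.primal_objective() - oracle_obj) < 1e-6
            assert abs(model.dual_objective() - oracle_obj) < 1e-6
            res = model.kkt_residuals()
            assert max(res.values()) < 1e-6
            assert model.expansion_residual() < 1e-8

    def test_agrees_with_libsvm(self, rng):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=20) > 0, 1.0, -1.0)
        model = fit_linear_svm_arrays(X, y, C=1.0)
        ref = sklearn_svm.SVC(kernel="linear", C=1.0, tol=1e-8).fit(X, y)
        np.testing.assert_allclose(model.weights, ref.coef_.ravel(), atol=1e-4)
        assert abs(model.bias - ref.intercept_[0]) < 1e-3

    def test_weight_magnitudes(self, rng):
        # axis 0 separates perfectly, axis 1 is noise, axis 2 is constant
        x0 = np.concatenate([rng.normal(size=8) + 3, rng.normal(size=8) - 3])
        X = np.column_stack([x0, rng.normal(size=16), np.full(16, 5.0)])
        y = np.array([1.0] * 8 + [-1.0] * 8)
        mags = svm_weight_magnitudes(fit_linear_svm_arrays(X, y, C=1.0))
        assert mags[0] > mags[1]
        assert mags[2] < 1e-8

    def test_duplicated_feature_gets_equal_weight(self, rng):
        x0 = np.concatenate([rng.normal(size=6) + 2, rng.normal(size=6) - 2])
        X = np.column_stack([x0, x0])
        y = np.array([1.0] * 6 + [-1.0] * 6)
        mags = svm_weight_magnitudes(fit_linear_svm_arrays(X, y, C=1.0))
        assert abs(mags[0] - mags[1]) < 1e-8

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            fit_linear_svm_arrays(np.zeros((2, 1)), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            fit_linear_svm_arrays(
                np.zeros((2, 1)), np.array([-1.0, 1.0]), C=0.0
            )


# ---------------------------------------------------------------------------
# NSC
# ---------------------------------------------------------------------------

def nearest_centroid_oracle(model, X):
    """Plain standardized nearest-centroid predictions (no shrinkage)."""
    denom = (model.pooled_sd + model.s0) ** 2
    disc = np.column_stack([
        np.sum((X - model.class_centroids[k]) ** 2 / denom, axis=1)
        - 2.0 * np.log(model.priors[k])
        for k in (0, 1)
    ])
    return (disc[:, 1] <= disc[:, 0]).astype(np.int8)


class TestNSC:
    def _data(self, rng, n=20, d=6):
        X = rng.normal(size=(n, d))
        y = np.array([0] * (n // 2) + [1] * (n - n // 2))
        X[y == 1, 0] += 2.0
        return X, y

    def test_zero_shrinkage_equals_nearest_centroid(self, rng):
        X, y = self._data(rng)
        model = fit_nsc_arrays(X, y, delta=0.0)
        Xq = rng.normal(size=(15, 6))
        np.testing.assert_array_equal(
            model.predict(Xq), nearest_centroid_oracle(model, Xq)
        )
        np.testing.assert_array_equal(model.shrunken_scores, model.scores)

    def test_total_shrinkage_predicts_prior(self, rng):
        X, y = self._data(rng, n=21)  # 10 NEG, 11 POS
        model = fit_nsc_arrays(X, y, delta=0.0)
        big = float(np.abs(model.scores).max()) + 1.0
        shrunk = fit_nsc_arrays(X, y, delta=big)
        assert not shrunk.active_genes.any()
        pred = shrunk.predict(rng.normal(size=(25, 6)))
        assert (pred == 1).all()  # POSITIVE is the majority class

    def test_hand_computed_scores(self):
        # 2 genes, 2+2 samples; all quantities computed by hand
        X = np.array([[0.0, 10.0], [2.0, 10.0], [4.0, 14.0], [6.0, 14.0]])
        y = np.array([0, 0, 1, 1])
        # centroids: gene0: 1 vs 5 (overall 3); gene1: 10 vs 14 (overall 12)
        # within scatter gene0: 2+2=4 -> s^2 = 4/2 = 2; gene1: 0 -> s = 0
        # median s_i -> s0 = (sqrt(2)+0)/2
        s = np.array([np.sqrt(2.0), 0.0])
        s0 = s.mean()
        mk = np.sqrt(1 / 2 - 1 / 4)
        d_expect = np.array([
            [(1 - 3), (10 - 12)],
            [(5 - 3), (14 - 12)],
        ]) / (mk * (s + s0))
        model = fit_nsc_arrays(X, y)
        np.testing.assert_allclose(model.scores, d_expect, atol=1e-12)
        delta = 1.0
        shrunk = fit_nsc_arrays(X, y, delta=delta)
        expect = np.sign(d_expect) * np.maximum(np.abs(d_expect) - delta, 0.0)
        np.testing.assert_allclose(shrunk.shrunken_scores, expect, atol=1e-12)

    def test_soft_threshold_never_changes_sign_and_is_monotone(self, rng):
        X, y = self._data(rng)
        base = fit_nsc_arrays(X, y, delta=0.0)
        prev_active = base.active_genes.sum()
        for delta in np.linspace(0.0, np.abs(base.scores).max() + 0.1, 8):
            m = fit_nsc_arrays(X, y, delta=float(delta))
            assert np.all(m.shrunken_scores * base.scores >= 0)
            assert np.all(np.abs(m.shrunken_scores) <= np.abs(base.scores) + 1e-12)
            active = m.active_genes.sum()
            assert active <= prev_active
            prev_active = active

    def test_error_conditions(self, rng):
        X, y = self._data(rng)
        with pytest.raises(ValueError):
            fit_nsc_arrays(X, y, delta=-1.0)
        with pytest.raises(ValueError):
            fit_nsc_arrays(X[:3], np.array([0, 0, 1]))
        model = fit_nsc_arrays(X, y)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 3)))
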