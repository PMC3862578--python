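"""Linear discriminant analysis with a pooled covariance matrix.

Two-class equal-covariance Gaussian classifier: class means and priors are
the sample estimates, the shared covariance is the pooled within-class
scatter divided by n - K.  Parameter-free, linear, and stable at the tiny
sample sizes typical of expression studies — which is why it serves as the
wrapper search's performance measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ..data import LabeledDataset

__all__ = ["LDAModel", "fit_lda", "fit_lda_arrays", "lda_predict"]

#: relative ridge added to a pooled covariance that is singular at working
#: precision (duplicate or constant genes inside a small training fold)
RIDGE_REL = 1e-8


@dataclass(frozen=True)
class LDAModel:
    """means[k], pooled covariance, priors for classes k=0 (NEGATIVE), 1 (POSITIVE);
    ``ridge`` is the diagonal loading actually applied (0 when Sigma was SPD)."""

    means: np.ndarray  # (2, d)
    pooled_cov: np.ndarray  # (d, d), before ridge
    priors: np.ndarray  # (2,)
    ridge: float

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def _regularized_cov(self) -> np.ndarray:
        S = self.pooled_cov
        if self.ridge:
            S = S + self.ridge * np.eye(S.shape[0])
        return S

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """g_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k, shape (n, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        cf = cho_factor(self._regularized_cov())
        A = cho_solve(cf, self.means.T)  # (d, 2) = S^-1 mu_k
        return X @ A - 0.5 * np.sum(self.means.T * A, axis=0) + np.log(self.priors)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """0/1 labels; exact discriminant ties go to POSITIVE (class 1)."""
        g = self.discriminants(X)
        return (g[:, 1] >= g[:, 0]).astype(np.int8)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(class k | x) under the equal-covariance Gaussian model, (n, 2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        cf = cho_factor(self._regularized_cov())
        # log pi_k - (x - mu_k)' S^-1 (x - mu_k) / 2, common constant dropped
        logp = np.empty((X.shape[0], 2))
        for k in range(2):
            diff = X - self.means[k]
            logp[:, k] = np.log(self.priors[k]) - 0.5 * np.sum(
                diff * cho_solve(cf, diff.T).T, axis=1
            )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def linear_boundary(self) -> tuple[np.ndarray, float]:
        """(w, c) with g_1(x) - g_0(x) = w.x + c: w = S^-1 (mu_1 - mu_0)."""
        cf = cho_factor(self._regularized_cov())
        w = cho_solve(cf, self.means[1] - self.means[0])
        c = -0.5 * float((self.means[1] + self.means[0]) @ w) + float(
            np.log(self.priors[1] / self.priors[0])
        )
        return w, c


def fit_lda_arrays(X: np.ndarray, y: np.ndarray) -> LDAModel:
    """Fit from a samples x features matrix and 0/1 labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    n, d = X.shape
    counts = np.array([(y == 0).sum(), (y == 1).sum()])
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to pool covariance")
    means = np.vstack([X[y == k].mean(axis=0) for k in (0, 1)])
    scatter = np.zeros((d, d))
    for k in (0, 1):
        Z = X[y == k] - means[k]
        scatter += Z.T @ Z
    pooled = scatter / (n - 2)
    ridge = 0.0
    S = pooled
    scale = max(float(np.diag(pooled).max(initial=0.0)), np.finfo(float).tiny)
    for _ in range(40):
        try:
            cf, _ = cho_factor(S)
            # exact singularity can still factor; reject vanishing pivots
            if float((np.diag(cf) ** 2).min()) > 1e-12 * scale:
                break
        except np.linalg.LinAlgError:
            pass
        step = max(RIDGE_REL * np.trace(pooled) / d, np.finfo(float).tiny)
        ridge = step if ridge == 0.0 else ridge * 10.0
        S = pooled + ridge * np.eye(d)
    else:
        raise np.linalg.LinAlgError("pooled covariance could not be regularized")
    priors = counts / n
    return LDAModel(means=means, pooled_cov=pooled, priors=priors, ridge=ridge)


def fit_lda(data: LabeledDataset) -> LDAModel:
    if data.labels is None:
        raise ValueError("dataset has no labels")
    return fit_lda_arrays(data.matrix, data.labels)


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
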