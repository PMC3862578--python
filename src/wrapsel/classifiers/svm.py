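"""Soft-margin linear SVM solved in its dual form.

The primal problem is min_(w,b,xi) ||w||^2 / 2 + C * sum_i xi_i subject to
y_i (w.x_i + b) >= 1 - xi_i and xi_i >= 0.  The dual is a box-constrained QP
with one equality constraint, solved here by sequential minimal optimization
with maximal-violating-pair working-set selection (the LIBSVM scheme).  The
weight vector is recovered as the label-weighted expansion over the support
vectors, w = sum_i alpha_i y_i x_i; its per-feature magnitudes |w_i| are the
relevance scores used for tie-breaking and for recursive feature
elimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import LabeledDataset

__all__ = ["SVMModel", "fit_linear_svm", "fit_linear_svm_arrays", "svm_weight_magnitudes"]


class SVMConvergenceError(RuntimeError):
    """Solver failed to reach the KKT tolerance; carries the residual."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"SMO did not converge: KKT violation {residual:.3e} > tol {tol:.3e}"
        )


@dataclass(frozen=True)
class SVMModel:
    weights: np.ndarray  # (d,)
    bias: float
    alpha: np.ndarray  # (n,) dual coefficients in [0, C]
    C: float
    X: np.ndarray  # training inputs (n, d)
    y: np.ndarray  # training labels in {-1, +1}

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1/-1; points exactly on the hyperplane go to +1."""
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)

    @property
    def slacks(self) -> np.ndarray:
        """xi_i = max(0, 1 - y_i f(x_i)), derived from the solution."""
        return np.maximum(0.0, 1.0 - self.y * self.decision_function(self.X))

    @property
    def margin(self) -> float:
        """Geometric margin 2 / ||w||."""
        return 2.0 / float(np.linalg.norm(self.weights))

    def primal_objective(self) -> float:
        return 0.5 * float(self.weights @ self.weights) + self.C * float(
            self.slacks.sum()
        )

    def dual_objective(self) -> float:
        v = self.alpha * self.y
        return float(self.alpha.sum() - 0.5 * v @ (self.X @ (self.X.T @ v)))

    def expansion_residual(self) -> float:
        """max |w - sum_i alpha_i y_i x_i|: zero by construction, reported
        so tests can assert the expansion identity independently."""
        w = (self.alpha * self.y) @ self.X
        return float(np.abs(self.weights - w).max(initial=0.0))

    def kkt_residuals(self) -> dict[str, float]:
        """Worst-case violations of the KKT conditions at the solution."""
        f = self.decision_function(self.X)
        m = self.y * f  # functional margins
        box = max(float((-self.alpha).max(initial=0.0)),
                  float((self.alpha - self.C).max(initial=0.0)))
        equality = abs(float(self.alpha @ self.y))
        # alpha_i = 0  -> y_i f_i >= 1;  0 < a < C -> y_i f_i = 1;  a = C -> <= 1
        interior = (self.alpha > 1e-9 * self.C) & (self.alpha < (1 - 1e-9) * self.C)
        lower = self.alpha <= 1e-9 * self.C
        upper = self.alpha >= (1 - 1e-9) * self.C
        r_low = float(np.maximum(0.0, 1.0 - m[lower]).max(initial=0.0))
        r_int = float(np.abs(1.0 - m[interior]).max(initial=0.0))
        r_up = float(np.maximum(0.0, m[upper] - 1.0).max(initial=0.0))
        return {
            "box": box,
            "equality": equality,
            "complementarity": max(r_low, r_int, r_up),
            "duality_gap": self.primal_objective() - self.dual_objective(),
        }


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int):
    """Minimize alpha'Q alpha / 2 - 1'alpha s.t. y'alpha = 0, 0 <= alpha <= C,
    with Q = (y y') * K, by maximal-violating-pair SMO.  Returns (alpha, m, M)
    where [M, m] brackets the optimal -b."""
    n = y.size
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad_i = (Q alpha)_i - 1
    Qcols = (y[:, None] * y[None, :]) * K
    tau = 1e-12
    for _ in range(max_iter):
        yg = -y * grad
        up = ((y > 0) & (alpha < C)) | ((y < 0) & (alpha > 0))
        low = ((y > 0) & (alpha > 0)) | ((y < 0) & (alpha < C))
        if not up.any() or not low.any():
            m = yg[up].max() if up.any() else -np.inf
            M = yg[low].min() if low.any() else np.inf
            return alpha, m, M
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(yg[low])])
        m, M = yg[i], yg[j]
        if m - M < tol:
            return alpha, m, M
        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] != y[j]:
            quad = Qcols[i, i] + Qcols[j, j] + 2.0 * Qcols[i, j]
            if quad <= 0:
                quad = tau
            delta = (-grad[i] - grad[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
            if diff > 0:
                if ai > C:
                    ai, aj = C, C - diff
            else:
                if aj > C:
                    aj, ai = C, C + diff
        else:
            quad = Qcols[i, i] + Qcols[j, j] - 2.0 * Qcols[i, j]
            if quad <= 0:
                quad = tau
            delta = (grad[i] - grad[j]) / quad
            total = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if total > C:
                if ai > C:
                    ai, aj = C, total - C
            else:
                if aj < 0:
                    aj, ai = 0.0, total
            if total > C:
                if aj > C:
                    aj, ai = C, total - C
            else:
                if ai < 0:
                    ai, aj = 0.0, total
        alpha[i], alpha[j] = ai, aj
        grad += Qcols[:, i] * (ai - ai_old) + Qcols[:, j] * (aj - aj_old)
    raise SVMConvergenceError(float(m - M), tol)


def fit_linear_svm_arrays(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200_000,
) -> SVMModel:
    """Fit from samples x features and labels in {-1, +1} (0/1 accepted)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) <= {0.0, 1.0}:
        y = np.where(y > 0, 1.0, -1.0)
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1} (or 0/1)")
    if (y > 0).sum() < 1 or (y < 0).sum() < 1:
        raise ValueError("need at least one sample per class")
    if not C > 0:
        raise ValueError("C must be positive")
    K = X @ X.T
    alpha, m, M = _smo(K, y, C, tol, max_iter)
    w = (alpha * y) @ X
    # bias from margin support vectors (0 < alpha < C), averaged; otherwise
    # the midpoint of the KKT interval [M, m] for -b.
    eps = 1e-8 * C
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        b = float(np.mean(y[free] - X[free] @ w))
    else:
        finite = [v for v in (m, M) if np.isfinite(v)]
        b = float(np.mean(finite)) if finite else 0.0
    return SVMModel(weights=w, bias=b, alpha=alpha, C=float(C), X=X, y=y)


def fit_linear_svm(data: LabeledDataset, C: float = 1.0, **kwargs) -> SVMModel:
    if data.labels is None:
        raise ValueError("dataset has no labels")
    return fit_linear_svm_arrays(data.matrix, data.y_signed(), C=C, **kwargs)


def svm_weight_magnitudes(model: SVMModel) -> np.ndarray:
    """Per-feature relevance |w_i| in the model's feature order."""
    return np.abs(model.weights)
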