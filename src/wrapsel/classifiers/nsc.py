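"""Nearest shrunken centroid classification (the PAM-style comparator).

Per-gene standardized class-centroid scores d_ik = (xbar_ik - xbar_i) /
(m_k (s_i + s0)) are soft-thresholded by Delta; genes whose scores shrink to
zero for every class drop out of the classifier, which is what makes the
method a gene selector as well as a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..data import LabeledDataset

__all__ = ["NSCModel", "fit_nsc", "fit_nsc_arrays", "nsc_predict"]


@dataclass(frozen=True)
class NSCModel:
    overall_centroid: np.ndarray  # (d,)
    class_centroids: np.ndarray  # (2, d), k=0 NEGATIVE, k=1 POSITIVE
    pooled_sd: np.ndarray  # (d,) per-gene pooled within-class SD
    s0: float
    delta: float
    scores: np.ndarray  # (2, d) unshrunken d_ik
    shrunken_scores: np.ndarray  # (2, d) d'_ik
    priors: np.ndarray  # (2,)
    m_k: np.ndarray  # (2,) sqrt(1/n_k - 1/n)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        """xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik, shape (2, d)."""
        return self.overall_centroid + (
            self.m_k[:, None] * (self.pooled_sd + self.s0) * self.shrunken_scores
        )

    @property
    def active_genes(self) -> np.ndarray:
        """Boolean mask of genes with a nonzero shrunken score in some class."""
        return (self.shrunken_scores != 0).any(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """argmin_k sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k;
        ties go to POSITIVE (class 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.overall_centroid.size:
            raise ValueError(
                f"expected {self.overall_centroid.size} features, got {X.shape[1]}"
            )
        cent = self.shrunken_centroids
        denom = (self.pooled_sd + self.s0) ** 2
        disc = np.empty((X.shape[0], 2))
        for k in (0, 1):
            disc[:, k] = np.sum((X - cent[k]) ** 2 / denom, axis=1) - 2.0 * np.log(
                self.priors[k]
            )
        return (disc[:, 1] <= disc[:, 0]).astype(np.int8)


def fit_nsc_arrays(
    X: np.ndarray, y: np.ndarray, delta: float = 0.0, s0: float | None = None
) -> NSCModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    n, d = X.shape
    counts = np.array([(y == 0).sum(), (y == 1).sum()])
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    overall = X.mean(axis=0)
    cents = np.vstack([X[y == k].mean(axis=0) for k in (0, 1)])
    within = np.zeros(d)
    for k in (0, 1):
        within += ((X[y == k] - cents[k]) ** 2).sum(axis=0)
    sd = np.sqrt(within / (n - 2))
    if s0 is None:
        s0 = float(np.median(sd))
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    m_k = np.sqrt(1.0 / counts - 1.0 / n)
    denom = m_k[:, None] * (sd + s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, (cents - overall) / denom, 0.0)
    shrunken = np.sign(scores) * np.maximum(np.abs(scores) - delta, 0.0)
    return NSCModel(
        overall_centroid=overall,
        class_centroids=cents,
        pooled_sd=sd,
        s0=float(s0),
        delta=float(delta),
        scores=scores,
        shrunken_scores=shrunken,
        priors=counts / n,
        m_k=m_k,
    )


def fit_nsc(
    data: LabeledDataset, delta: float = 0.0, s0: float | None = None
) -> NSCModel:
    if data.labels is None:
        raise ValueError("dataset has no labels")
    return fit_nsc_arrays(data.matrix, data.labels, delta=delta, s0=s0)


def nsc_predict(model: NSCModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
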