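"""Repeated stratified k-fold cross-validation.

The r x k mean fold accuracy of LDA is the performance measure maximized by
the wrapper search (5x5 cv by default; 10x10 cv runs through the same code
path).  One plan is built per selection run and reused for every subset
evaluation so that competing subsets are compared on identical partitions —
which is what makes exact ties between subsets well-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import LabeledDataset
from .classifiers.lda import fit_lda_arrays

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "cv_accuracy",
    "cv_fold_correct_counts",
    "measure_from_counts",
]


@dataclass(frozen=True)
class CVPlan:
    """Per-round, per-fold held-out sample indices.

    ``folds[r][f]`` is the test-index array of fold f in round r; within a
    round the folds are disjoint and cover all samples, fold sizes differ by
    at most one, and per-class fold counts differ by at most one.
    """

    k: int
    r: int
    seed: int
    folds: tuple[tuple[np.ndarray, ...], ...]

    @property
    def n_samples(self) -> int:
        return sum(len(f) for f in self.folds[0])

    def fold_sizes(self) -> list[list[int]]:
        return [[len(f) for f in round_] for round_ in self.folds]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "r": self.r,
            "seed": self.seed,
            "folds": [[f.tolist() for f in round_] for round_ in self.folds],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")


def make_cv_plan(labels: np.ndarray, k: int, r: int, seed: int) -> CVPlan:
    """Seeded stratified partitions: each class is shuffled and dealt
    cyclically to folds, the dealing position carrying over between classes
    so overall fold sizes also differ by at most one."""
    y = np.asarray(labels)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if r < 1:
        raise ValueError("r must be >= 1")
    rng = np.random.default_rng(seed)
    rounds = []
    for _ in range(r):
        assignment = np.empty(n, dtype=np.intp)
        pos = 0  # global dealing position, continued across classes
        for cls in (1, 0):
            members = np.flatnonzero(y == cls)
            members = rng.permutation(members)
            for m in members:
                assignment[m] = pos % k
                pos += 1
        folds = tuple(np.flatnonzero(assignment == f) for f in range(k))
        for f, test_idx in enumerate(folds):
            train_y = np.delete(y, test_idx)
            if (train_y == 1).sum() == 0 or (train_y == 0).sum() == 0:
                raise ValueError(
                    f"fold {f}: training part is missing a class "
                    "(k too large for these class counts)"
                )
        rounds.append(folds)
    return CVPlan(k=k, r=r, seed=seed, folds=tuple(rounds))


def cv_fold_correct_counts(
    X: np.ndarray, y: np.ndarray, plan: CVPlan
) -> tuple[np.ndarray, np.ndarray]:
    """LDA correct-prediction count and size per (round, fold).

    Returns integer arrays (r*k,) of correct counts and fold sizes, in plan
    order — the exact building blocks of the performance measure.
    """
    counts = []
    sizes = []
    for ri, round_ in enumerate(plan.folds):
        for fi, test_idx in enumerate(round_):
            mask = np.ones(y.size, dtype=bool)
            mask[test_idx] = False
            try:
                model = fit_lda_arrays(X[mask], y[mask])
            except Exception as exc:
                raise RuntimeError(
                    f"LDA fit failed in round {ri}, fold {fi}: {exc}"
                ) from exc
            pred = model.predict(X[test_idx])
            counts.append(int((pred == y[test_idx]).sum()))
            sizes.append(len(test_idx))
    return np.array(counts), np.array(sizes)


def measure_from_counts(counts: Sequence[int], sizes: Sequence[int]) -> Fraction:
    """Unweighted mean of fold accuracies as an exact rational."""
    total = sum(Fraction(int(c), int(s)) for c, s in zip(counts, sizes))
    return total / len(list(counts))


def cv_accuracy(
    data: LabeledDataset,
    gene_subset: Sequence[str],
    plan: CVPlan,
    classifier: str = "lda",
    pooled: bool = False,
) -> float:
    """Mean cross-validated accuracy of LDA on the gene subset.

    ``pooled=True`` instead pools all held-out predictions and returns the
    overall correct fraction; with near-equal fold sizes the two differ by
    at most ~1e-2.
    """
    if classifier != "lda":
        raise ValueError("only the LDA measure is supported")
    if len(gene_subset) == 0:
        raise ValueError("gene_subset must be non-empty")
    if data.labels is None:
        raise ValueError("dataset has no labels")
    idx = data.gene_index(gene_subset)
    X = data.matrix[:, idx]
    counts, sizes = cv_fold_correct_counts(X, data.labels, plan)
    if pooled:
        return float(counts.sum() / sizes.sum())
    return float(measure_from_counts(counts, sizes))
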