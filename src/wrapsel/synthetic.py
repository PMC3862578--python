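"""Synthetic two-class expression data with known planted structure.

The generator emulates the shape of small two-class microarray studies:
tens of samples, 10^2-10^4 genes on a log2-like intensity scale, a small set
of class-informative genes whose class means differ by a chosen effect size
in noise-SD units, the rest pure Gaussian noise shared by both classes, and
optionally exact duplicate columns of planted genes to provoke ties in
cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import LabeledDataset
from .interpret import min_single_threshold_error

__all__ = ["SyntheticSpec", "generate_two_class_dataset", "plant_threshold_separator"]

#: baseline intensity; cosmetic, chosen to resemble log2 microarray values
BASELINE = 7.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``planted`` lists (gene index, effect size delta) pairs; delta is the
    class-mean difference in units of ``noise_sd``.  ``n_duplicates`` exact
    copies of planted genes overwrite the highest-index noise columns,
    cycling over the planted genes in order.
    """

    n_pos: int
    n_neg: int
    n_genes: int
    planted: tuple[tuple[int, float], ...] = ()
    noise_sd: float = 1.0
    n_duplicates: int = 0
    seed: int = 0
    baseline: float = BASELINE

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(
            (int(j), float(d)) for j, d in self.planted
        ))
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 samples per class")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        idx = [j for j, _ in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted gene indices must be distinct")
        if any(j < 0 or j >= self.n_genes for j in idx):
            raise ValueError("planted gene index out of range")
        if any(not np.isfinite(d) for _, d in self.planted):
            raise ValueError("planted effect sizes must be finite")
        if self.n_duplicates and not self.planted:
            raise ValueError("duplicates require at least one planted gene")
        if self.n_duplicates > self.n_genes - len(self.planted):
            raise ValueError("not enough noise columns to hold duplicates")

    def planted_gene_ids(self) -> tuple[str, ...]:
        return tuple(_gene_id(j, self.n_genes) for j, _ in self.planted)

    def duplicate_gene_ids(self) -> tuple[str, ...]:
        return tuple(
            _gene_id(self.n_genes - 1 - i, self.n_genes)
            for i in range(self.n_duplicates)
        )


def _gene_id(j: int, n_genes: int) -> str:
    width = max(4, len(str(n_genes - 1)))
    return f"g{j:0{width}d}"


def generate_two_class_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Draw one dataset from the spec; same spec + seed is bit-identical.

    Noise genes are i.i.d. Gaussian(baseline, noise_sd^2) in both classes;
    planted gene j gets +delta_j * noise_sd added to the POSITIVE class, so
    the population standardized mean difference is exactly delta_j.  Labels
    start as n_pos POSITIVEs then n_neg NEGATIVEs and sample order is then
    shuffled with the same seeded stream.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    X = spec.baseline + spec.noise_sd * rng.standard_normal((n, spec.n_genes))
    y = np.concatenate(
        [np.ones(spec.n_pos, dtype=np.int8), np.zeros(spec.n_neg, dtype=np.int8)]
    )
    for j, delta in spec.planted:
        X[y == 1, j] += delta * spec.noise_sd
    planted_idx = [j for j, _ in spec.planted]
    for i in range(spec.n_duplicates):
        src = planted_idx[i % len(planted_idx)]
        X[:, spec.n_genes - 1 - i] = X[:, src]
    perm = rng.permutation(n)
    gene_ids = tuple(_gene_id(j, spec.n_genes) for j in range(spec.n_genes))
    sample_ids = tuple(f"s{i:03d}" for i in range(n))
    return LabeledDataset(
        matrix=X[perm], gene_ids=gene_ids, sample_ids=sample_ids, labels=y[perm]
    )


def plant_threshold_separator(
    n_pos: int, n_neg: int, exceptions: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-gene values + labels whose best threshold makes exactly
    ``exceptions`` mistakes.

    Returns (values, labels): strictly increasing distinct values and 0/1
    labels such that the minimum over all cut points and both orientations of
    the misclassification count equals ``exceptions``.  Feasibility: writing
    e = exceptions, an arrangement with minimum error e exists iff
    e <= min(n_pos, n_neg) and 2e < n_pos + n_neg (the latter excludes only
    the balanced corner e = n_pos = n_neg).
    """
    e = int(exceptions)
    if e < 0:
        raise ValueError("exceptions must be >= 0")
    if e > min(n_pos, n_neg) or 2 * e >= n_pos + n_neg:
        raise ValueError(
            f"no arrangement of {n_pos}+{n_neg} labels has minimum "
            f"threshold error {e}"
        )
    # POSITIVE block, e alternating NEG/POS pairs, NEGATIVE block:
    # the positives-low orientation attains error e at the block boundary and
    # no cut or orientation does better.
    labels = np.array(
        [1] * (n_pos - e) + [0, 1] * e + [0] * (n_neg - e), dtype=np.int8
    )
    achieved = min_single_threshold_error(labels)
    if achieved != e:  # defensive: construction is proven, sweep re-checks
        raise AssertionError(
            f"constructed arrangement has error {achieved}, wanted {e}"
        )
    rng = np.random.default_rng(seed)
    steps = rng.uniform(0.1, 1.0, size=n_pos + n_neg)
    values = BASELINE + np.cumsum(steps)
    return values, labels
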