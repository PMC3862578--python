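"""Post-selection interpretation: rank statistics, chance-separation
probability, and a depth-limited CART decision tree.

The chance-separation probability answers: if a gene carries no class
information, how likely is it that sorting samples by that gene's expression
yields a label sequence that a single threshold can split with at most *e*
mistakes?  Extended to "any of G genes" under independence, this quantifies
how surprised one should be by a near-perfect single-gene separator in a
genome-wide scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from .data import POSITIVE, NEGATIVE, LabeledDataset

__all__ = [
    "mann_whitney",
    "spearman_rho",
    "min_single_threshold_error",
    "single_gene_separation_probability",
    "any_gene_separation_probability",
    "GeneStatReport",
    "gene_stat_report",
    "DecisionTree",
    "TreeNode",
    "TreeLeaf",
    "fit_depth2_tree",
    "render_tree",
]


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U statistic of x, p-value).

    Exact permutation null when min(n1, n2) <= 8 and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  ``alternative``: "two_sided", "greater" (x tends larger),
    or "less".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    NaN (with a warning) when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("zero rank variance: Spearman rho undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Chance-separation probability
# ---------------------------------------------------------------------------

def min_single_threshold_error(labels_in_value_order: Sequence[int]) -> int:
    """Minimum misclassifications of a single threshold on a sorted gene.

    ``labels_in_value_order``: 0/1 labels of the samples ordered by the
    gene's expression value.  All n+1 cut points and both orientations
    (positives-low / positives-high) are swept.
    """
    lab = np.asarray(labels_in_value_order, dtype=int)
    n = lab.size
    n1 = int(lab.sum())
    n2 = n - n1
    ones_prefix = np.concatenate([[0], np.cumsum(lab)])  # ones in the first c
    c = np.arange(n + 1)
    # positives predicted low: errors = zeros in prefix + ones in suffix
    err_low = (c - ones_prefix) + (n1 - ones_prefix)
    # positives predicted high: errors = ones in prefix + zeros in suffix
    err_high = ones_prefix + (n2 - (c - ones_prefix))
    return int(min(err_low.min(), err_high.min()))


@lru_cache(maxsize=None)
def _separable_arrangement_count(n1: int, n2: int, e: int) -> int:
    """Number of 0/1 arrangements (n1 ones, n2 zeros) whose minimum
    single-threshold error is <= e, by dynamic programming.

    For an arrangement scanned left to right let o(c) be the ones among the
    first c values and s(c) = c - 2*o(c).  The threshold error at cut c is
    n1 + s(c) for the positives-low orientation and n2 - s(c) for
    positives-high, so the minimum over all cuts is
    min(n1 + min_c s, n2 - max_c s).  The DP tracks (ones so far, running
    min of s, running max of s); s changes by +/-1 per step, so the state
    space is O(n^3) and counts are exact integers.
    """
    n = n1 + n2
    # state: (ones, -min_s, max_s) -> count; s(0)=0 so min_s<=0<=max_s
    states: dict[tuple[int, int, int], int] = {(0, 0, 0): 1}
    for pos in range(n):
        nxt: dict[tuple[int, int, int], int] = {}
        for (o, a, b), cnt in states.items():
            s = (pos - o) - o  # current s(pos); a = -min_s, b = max_s
            # place a one (label 1): s -> s-1
            if o < n1:
                key = (o + 1, max(a, -(s - 1)), b)
                nxt[key] = nxt.get(key, 0) + cnt
            # place a zero: s -> s+1
            if (pos - o) < n2:
                key = (o, a, max(b, s + 1))
                nxt[key] = nxt.get(key, 0) + cnt
        states = nxt
    total = 0
    for (o, a, b), cnt in states.items():
        if min(n1 - a, n2 - b) <= e:
            total += cnt
    return total


def single_gene_separation_probability(n1: int, n2: int, e: int) -> float:
    """P(min single-threshold error <= e) for a label-uninformative gene.

    The gene's values are assumed distinct, so the induced label arrangement
    is uniform over the C(n1+n2, n1) orderings.
    """
    if n1 < 1 or n2 < 1 or e < 0:
        raise ValueError("need n1, n2 >= 1 and e >= 0")
    if e >= min(n1, n2):
        return 1.0
    count = _separable_arrangement_count(n1, n2, e)
    return float(Fraction(count, comb(n1 + n2, n1)))


def any_gene_separation_probability(n1: int, n2: int, e: int, n_genes: int) -> float:
    """P(at least one of ``n_genes`` independent null genes separates with
    <= e exceptions) = 1 - (1 - p_single)^G."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    p1 = single_gene_separation_probability(n1, n2, e)
    # expm1/log1p keeps precision when p1 is tiny and G is huge
    return float(-np.expm1(n_genes * np.log1p(-p1))) if p1 < 1.0 else 1.0


# ---------------------------------------------------------------------------
# Per-gene statistics report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneStatReport:
    gene_id: str
    median_positive: float
    median_negative: float
    statistic: float
    p_value: float
    significant: bool


def gene_stat_report(
    data: LabeledDataset,
    gene_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    alternative: str = "two_sided",
) -> list[GeneStatReport]:
    """Mann-Whitney comparison of POSITIVE vs NEGATIVE expression per gene."""
    if data.labels is None:
        raise ValueError("dataset has no labels")
    if gene_ids is None:
        gene_ids = data.gene_ids
    idx = data.gene_index(gene_ids)
    pos = data.labels == 1
    out = []
    for g, j in zip(gene_ids, idx):
        x = data.matrix[pos, j]
        y = data.matrix[~pos, j]
        w, p = mann_whitney(x, y, alternative=alternative)
        out.append(
            GeneStatReport(
                gene_id=g,
                median_positive=float(np.median(x)),
                median_negative=float(np.median(y)),
                statistic=w,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Depth-limited CART
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeLeaf:
    label: str  # POSITIVE / NEGATIVE
    n_positive: int
    n_negative: int
    coverage: float  # fraction of all training samples reaching this leaf


@dataclass(frozen=True)
class TreeNode:
    gene_id: str
    threshold: float  # left branch: value < threshold
    left: "TreeNode | TreeLeaf"
    right: "TreeNode | TreeLeaf"


@dataclass(frozen=True)
class DecisionTree:
    root: TreeNode | TreeLeaf
    n_samples: int

    def predict(self, data: LabeledDataset) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(data.gene_ids)}
        out = np.empty(data.n_samples, dtype=np.int8)
        for i in range(data.n_samples):
            node = self.root
            while isinstance(node, TreeNode):
                node = (
                    node.left
                    if data.matrix[i, lookup[node.gene_id]] < node.threshold
                    else node.right
                )
            out[i] = 1 if node.label == POSITIVE else 0
        return out

    def leaves(self) -> list[TreeLeaf]:
        found: list[TreeLeaf] = []

        def walk(node):
            if isinstance(node, TreeLeaf):
                found.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return found


def _gini(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float, float] | None:
    """Best (gene column, threshold, weighted child impurity) by Gini.

    Thresholds are midpoints between consecutive distinct sorted values.
    Ties are broken by lower column index, then smaller threshold.  None if
    no split reduces impurity.
    """
    n = y.size
    parent = _gini(int(y.sum()), int(n - y.sum()))
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        ones = np.cumsum(ys)
        distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
        for i in distinct:
            thr = 0.5 * (xs[i] + xs[i + 1])
            lp = int(ones[i])
            ln = int(i + 1 - lp)
            rp = int(ones[-1] - lp)
            rn = int(n - i - 1 - rp)
            w = ((lp + ln) * _gini(lp, ln) + (rp + rn) * _gini(rp, rn)) / n
            if best is None or w < best[2] - 1e-15:
                best = (j, thr, w)
    if best is None or best[2] >= parent - 1e-15:
        return None
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    gene_ids: Sequence[str],
    depth: int,
    max_depth: int,
    n_total: int,
) -> TreeNode | TreeLeaf:
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if depth >= max_depth or n_pos == 0 or n_neg == 0:
        split = None
    else:
        split = _best_split(X, y)
    if split is None:
        label = POSITIVE if n_pos >= n_neg else NEGATIVE  # tie -> POSITIVE
        return TreeLeaf(label, n_pos, n_neg, y.size / n_total)
    j, thr, _ = split
    mask = X[:, j] < thr
    return TreeNode(
        gene_id=gene_ids[j],
        threshold=thr,
        left=_grow(X[mask], y[mask], gene_ids, depth + 1, max_depth, n_total),
        right=_grow(X[~mask], y[~mask], gene_ids, depth + 1, max_depth, n_total),
    )


def fit_depth2_tree(
    data: LabeledDataset, gene_subset: Sequence[str], max_depth: int = 2
) -> DecisionTree:
    """CART (Gini impurity, no pruning) capped at depth 2, restricted to the
    model genes — the interpretable summary of a selected subset."""
    if data.labels is None:
        raise ValueError("dataset has no labels")
    if len(gene_subset) == 0:
        raise ValueError("gene_subset must be non-empty")
    sub = data.subset_genes(list(gene_subset))
    root = _grow(
        sub.matrix, sub.labels.astype(np.int64), sub.gene_ids, 0, max_depth,
        sub.n_samples,
    )
    return DecisionTree(root=root, n_samples=sub.n_samples)


def render_tree(
    tree: DecisionTree, class_names: dict[str, str] | None = None
) -> str:
    """Plain-text rendering; thresholds shown to 1 decimal, counts and
    coverage per leaf."""
    names = class_names or {POSITIVE: POSITIVE, NEGATIVE: NEGATIVE}
    lines: list[str] = []

    def walk(node, indent: str) -> None:
        if isinstance(node, TreeLeaf):
            n = node.n_positive + node.n_negative
            lines.append(
                f"{indent}predict {names[node.label]} "
                f"[{names[POSITIVE]}: {node.n_positive}, "
                f"{names[NEGATIVE]}: {node.n_negative}; "
                f"coverage {100 * node.coverage:.0f}% ({n}/{tree.n_samples})]"
            )
        else:
            lines.append(f"{indent}{node.gene_id} < {node.threshold:.1f}?")
            lines.append(f"{indent}  yes ->")
            walk(node.left, indent + "    ")
            lines.append(f"{indent}  no  ->")
            walk(node.right, indent + "    ")

    walk(tree.root, "")
    return "\n".join(lines)
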