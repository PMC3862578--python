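"""Wrapper gene selection: interleaved forward-backward search with
margin-based tie-breaking, plus the SVM-RFE and NSC comparator selectors.

The search maximizes the repeated stratified cross-validated LDA accuracy.
In a forward stage every remaining candidate is scored joined to the current
subset and the best strictly-improving gene is accepted; backward stages
then repeatedly drop whichever gene's removal strictly improves the measure,
and dropped genes are never reconsidered.  Because the sample sizes are
tiny, the measure is a ratio of small integers and exact ties between
candidates are common; they are resolved by the magnitude of a linear SVM's
weight components (largest wins an ADD, smallest loses a REMOVE), with any
residual exact tie going to the lowest column index.

Candidate scoring within a stage is vectorised over candidates; the outcome
is a pure function of (data, plan, C) and is bit-identical across runs.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Sequence

import numpy as np

from .data import LabeledDataset, SelectionResult, TraceStep
from .classifiers.svm import fit_linear_svm_arrays, SVMConvergenceError
from .classifiers.nsc import fit_nsc_arrays
from .classifiers.lda import RIDGE_REL
from .resampling import CVPlan, cv_fold_correct_counts, measure_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "forward_backward_select",
    "margin_tiebreak",
    "svm_rfe_rank",
    "nsc_select",
]


# ---------------------------------------------------------------------------
# Batched LDA fold evaluation
# ---------------------------------------------------------------------------

def _solve_weights(cov: np.ndarray, diff: np.ndarray) -> np.ndarray:
    """Batched solve cov[b] w[b] = diff[b]; singular items get the relative
    ridge (same rule as the reference LDA fit)."""
    try:
        return np.linalg.solve(cov, diff[..., None])[..., 0]
    except np.linalg.LinAlgError:
        pass
    out = np.empty_like(diff)
    d = cov.shape[-1]
    eye = np.eye(d)
    for b in range(cov.shape[0]):
        S = cov[b]
        ridge = 0.0
        for _ in range(40):
            try:
                out[b] = np.linalg.solve(S, diff[b])
                break
            except np.linalg.LinAlgError:
                step = max(RIDGE_REL * np.trace(cov[b]) / d, np.finfo(float).tiny)
                ridge = step if ridge == 0.0 else ridge * 10.0
                S = cov[b] + ridge * eye
        else:
            raise
    return out


def _fold_correct_add(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    base: Sequence[int],
    cands: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """For every candidate column g, the per-fold LDA correct counts of the
    feature set base + [g].  Returns (counts (F, B) int, sizes (F,) int)."""
    base = list(base)
    dS = len(base)
    B = cands.size
    F = plan.r * plan.k
    counts = np.empty((F, B), dtype=np.int64)
    sizes = np.empty(F, dtype=np.int64)
    f = 0
    for round_ in plan.folds:
        for test_idx in round_:
            mask = np.ones(y.size, dtype=bool)
            mask[test_idx] = False
            ytr = y[mask]
            n_tr = int(mask.sum())
            n1 = int(ytr.sum())
            n0 = n_tr - n1
            A = X[np.ix_(mask, base)] if dS else np.empty((n_tr, 0))
            V = X[mask][:, cands]
            mA = np.vstack([
                A[ytr == 0].mean(axis=0) if dS else np.zeros(0),
                A[ytr == 1].mean(axis=0) if dS else np.zeros(0),
            ])
            mV = np.vstack([V[ytr == 0].mean(axis=0), V[ytr == 1].mean(axis=0)])
            S_AA = np.zeros((dS, dS))
            S_AV = np.zeros((dS, B))
            S_VV = np.zeros(B)
            for kcls in (0, 1):
                Ac = A[ytr == kcls] - mA[kcls]
                Vc = V[ytr == kcls] - mV[kcls]
                if dS:
                    S_AA += Ac.T @ Ac
                    S_AV += Ac.T @ Vc
                S_VV += (Vc ** 2).sum(axis=0)
            dof = n_tr - 2
            cov = np.empty((B, dS + 1, dS + 1))
            cov[:, :dS, :dS] = S_AA / dof
            cov[:, :dS, dS] = (S_AV / dof).T
            cov[:, dS, :dS] = (S_AV / dof).T
            cov[:, dS, dS] = S_VV / dof
            diff = np.empty((B, dS + 1))
            diff[:, :dS] = mA[1] - mA[0]
            diff[:, dS] = mV[1] - mV[0]
            w = _solve_weights(cov, diff)  # (B, d)
            mean_sum = np.empty((B, dS + 1))
            mean_sum[:, :dS] = mA[1] + mA[0]
            mean_sum[:, dS] = mV[1] + mV[0]
            c = -0.5 * np.sum(mean_sum * w, axis=1) + np.log(n1 / n0)
            Xte_base = X[np.ix_(test_idx, base)] if dS else np.empty((len(test_idx), 0))
            Xte_c = X[test_idx][:, cands]
            scores = Xte_base @ w[:, :dS].T + Xte_c * w[:, dS] + c  # (n_te, B)
            pred = (scores >= 0).astype(np.int8)
            counts[f] = (pred == y[test_idx, None]).sum(axis=0)
            sizes[f] = len(test_idx)
            f += 1
    return counts, sizes


def _measures_from_count_matrix(
    counts: np.ndarray, sizes: np.ndarray
) -> list[Fraction]:
    F = sizes.size
    return [
        sum(Fraction(int(counts[f, b]), int(sizes[f])) for f in range(F)) / F
        for b in range(counts.shape[1])
    ]


def _subset_measure(
    X: np.ndarray, y: np.ndarray, cols: Sequence[int], plan: CVPlan
) -> Fraction:
    counts, sizes = cv_fold_correct_counts(X[:, list(cols)], y, plan)
    return measure_from_counts(counts, sizes)


# ---------------------------------------------------------------------------
# Tie-breaking
# ---------------------------------------------------------------------------

def margin_tiebreak(
    data: LabeledDataset,
    base_subset: Sequence[str],
    tied_candidates: Sequence[str],
    mode: str,
    C: float = 1.0,
    joint: bool = True,
) -> str:
    """Resolve a measure tie by linear-SVM weight magnitudes.

    One SVM is fitted on base + all tied candidates for an ADD (or on the
    base subset for a REMOVE) and each tied gene is ranked by |w| at its own
    coordinate: ADD keeps the largest, REMOVE drops the smallest.  Residual
    exact ties go to the lowest column index.  ``joint=False`` instead fits
    one SVM per tied candidate on base + that candidate alone (the
    alternative reading for the all-singleton first stage).
    """
    if mode not in ("ADD", "REMOVE"):
        raise ValueError("mode must be ADD or REMOVE")
    tied = list(tied_candidates)
    if not tied:
        raise ValueError("need at least one tied candidate")
    if len(tied) == 1:
        return tied[0]
    col = {g: i for i, g in enumerate(data.gene_ids)}
    try:
        mags = _tiebreak_magnitudes(data, list(base_subset), tied, mode, C, joint)
    except (SVMConvergenceError, ValueError) as exc:
        logger.warning("tie-break SVM failed (%s); falling back to index rule", exc)
        return min(tied, key=lambda g: col[g])
    # sort key: ADD wants max |w|; REMOVE wants min |w|; ties -> lowest index
    if mode == "ADD":
        order = sorted(tied, key=lambda g: (-mags[g], col[g]))
    else:
        order = sorted(tied, key=lambda g: (mags[g], col[g]))
    return order[0]


def _tiebreak_magnitudes(data, base, tied, mode, C, joint):
    y = data.y_signed()
    if mode == "REMOVE" or joint:
        fit_genes = list(base) if mode == "REMOVE" else list(base) + tied
        idx = data.gene_index(fit_genes)
        model = fit_linear_svm_arrays(data.matrix[:, idx], y, C=C)
        pos = {g: i for i, g in enumerate(fit_genes)}
        return {g: abs(float(model.weights[pos[g]])) for g in tied}
    mags = {}
    for g in tied:
        fit_genes = list(base) + [g]
        idx = data.gene_index(fit_genes)
        model = fit_linear_svm_arrays(data.matrix[:, idx], y, C=C)
        mags[g] = abs(float(model.weights[-1]))
    return mags


# ---------------------------------------------------------------------------
# Forward-backward search
# ---------------------------------------------------------------------------

def forward_backward_select(
    data: LabeledDataset,
    plan: CVPlan,
    C: float = 1.0,
    joint_tiebreak: bool = True,
    backward_allow_equal: bool = False,
    forward_only: bool = False,
) -> SelectionResult:
    """Interleaved forward-backward wrapper search (greedy hill-climbing).

    Starting from the empty subset (whose measure is defined as the
    majority-class rate), each outer iteration adds the best
    strictly-improving candidate, then repeatedly removes genes while
    removal strictly improves the measure; removed genes are permanently
    excluded from later inclusion.  The search stops when neither stage
    changes the subset.  ``backward_allow_equal`` accepts equal-measure
    removals (a smaller subset at the same measure); ``forward_only``
    disables the backward stage (for ablation comparisons).
    """
    if data.labels is None:
        raise ValueError("dataset has no labels")
    X = data.matrix
    y = data.labels.astype(np.int64)
    gene_ids = data.gene_ids
    n_genes = len(gene_ids)
    config = {
        "method": "fb",
        "k": plan.k,
        "r": plan.r,
        "svm_C": C,
        "joint_tiebreak": joint_tiebreak,
        "backward_allow_equal": backward_allow_equal,
        "forward_only": forward_only,
    }
    if n_genes == 0:
        return SelectionResult(
            accepted=(), excluded=frozenset(), trace=(),
            final_measure=float("nan"), seed=plan.seed,
            config=config | {"empty_candidate_set": True},
        )
    n1 = int(y.sum())
    n0 = y.size - n1
    best: list[int] = []  # accepted column indices, acceptance order
    excluded: set[int] = set()
    best_measure = Fraction(max(n0, n1), n0 + n1)  # empty-set baseline
    trace: list[TraceStep] = []
    col_of = {g: i for i, g in enumerate(gene_ids)}

    def available() -> np.ndarray:
        out = np.ones(n_genes, dtype=bool)
        out[list(best)] = False
        if excluded:
            out[list(excluded)] = False
        return np.flatnonzero(out)

    while True:
        changed = False
        # --- forward stage: one gene may be added ---
        cands = available()
        if cands.size:
            counts, sizes = _fold_correct_add(X, y, plan, best, cands)
            measures = _measures_from_count_matrix(counts, sizes)
            top = max(measures)
            if top > best_measure:
                tied_cols = [int(cands[b]) for b, m in enumerate(measures) if m == top]
                chosen_id = margin_tiebreak(
                    data,
                    [gene_ids[j] for j in best],
                    [gene_ids[j] for j in tied_cols],
                    "ADD",
                    C=C,
                    joint=joint_tiebreak,
                )
                chosen = col_of[chosen_id]
                best.append(chosen)
                best_measure = top
                trace.append(TraceStep("ADD", chosen_id, float(top)))
                logger.debug(
                    "ADD %s -> measure %.4f (%d tied)",
                    chosen_id, float(top), len(tied_cols),
                )
                changed = True
        # --- backward stage: genes are removed while that improves ---
        if not forward_only:
            while len(best) > 0:
                removal_measures = []
                for j in best:
                    remaining = [c for c in best if c != j]
                    if remaining:
                        m = _subset_measure(X, y, remaining, plan)
                    else:
                        m = Fraction(max(n0, n1), n0 + n1)
                    removal_measures.append(m)
                top = max(removal_measures)
                improves = top > best_measure or (
                    backward_allow_equal and top == best_measure
                )
                if not improves:
                    break
                tied_cols = [
                    best[i] for i, m in enumerate(removal_measures) if m == top
                ]
                victim_id = margin_tiebreak(
                    data,
                    [gene_ids[j] for j in best],
                    [gene_ids[j] for j in tied_cols],
                    "REMOVE",
                    C=C,
                    joint=joint_tiebreak,
                )
                victim = col_of[victim_id]
                best.remove(victim)
                excluded.add(victim)
                if top > best_measure:
                    trace.append(TraceStep("REMOVE", victim_id, float(top)))
                best_measure = top
                logger.debug("REMOVE %s -> measure %.4f", victim_id, float(top))
                changed = True
        if not changed:
            break
    return SelectionResult(
        accepted=tuple(gene_ids[j] for j in best),
        excluded=frozenset(gene_ids[j] for j in excluded),
        trace=tuple(trace),
        final_measure=float(best_measure),
        seed=plan.seed,
        config=config,
    )


# ---------------------------------------------------------------------------
# SVM-RFE comparator
# ---------------------------------------------------------------------------

def svm_rfe_rank(
    data: LabeledDataset,
    C: float = 1.0,
    elimination_fraction: float = 0.0,
) -> list[str]:
    """Recursive feature elimination ranking, most relevant gene first.

    Repeatedly fits a linear SVM on the surviving genes and eliminates the
    lowest-|w| gene (or the lowest ``elimination_fraction`` of them per
    round while more than 50 genes survive).  |w| ties are eliminated lowest
    column index first, so for fully interchangeable genes the returned
    ranking is reverse column order.
    """
    if data.labels is None:
        raise ValueError("dataset has no labels")
    if data.n_genes < 2:
        raise ValueError("need at least 2 genes to rank")
    if not 0.0 <= elimination_fraction < 1.0:
        raise ValueError("elimination_fraction must be in [0, 1)")
    y = data.y_signed()
    surviving = list(range(data.n_genes))
    eliminated: list[int] = []  # elimination order, first-out first
    while len(surviving) > 1:
        model = fit_linear_svm_arrays(data.matrix[:, surviving], y, C=C)
        mags = np.abs(model.weights)
        n_drop = 1
        if elimination_fraction > 0 and len(surviving) > 50:
            n_drop = max(1, int(len(surviving) * elimination_fraction))
            n_drop = min(n_drop, len(surviving) - 1)
        # least relevant first; |w| ties resolved by lower original column
        order = sorted(range(len(surviving)), key=lambda i: (mags[i], surviving[i]))
        for i in order[:n_drop]:
            eliminated.append(surviving[i])
        drop = {surviving[i] for i in order[:n_drop]}
        surviving = [j for j in surviving if j not in drop]
    eliminated.extend(surviving)
    ranking = eliminated[::-1]  # last eliminated = most relevant
    return [data.gene_ids[j] for j in ranking]


# ---------------------------------------------------------------------------
# NSC comparator
# ---------------------------------------------------------------------------

def nsc_select(
    data: LabeledDataset,
    plan: CVPlan,
    grid_size: int = 30,
    s0: float | None = None,
) -> tuple[float, list[str], float]:
    """Shrinkage-threshold selection by cross-validated NSC accuracy.

    Evaluates NSC over a grid of thresholds from 0 to max |d_ik| (computed
    on the full data) and returns (Delta*, active gene ids at Delta*, cv
    accuracy at Delta*), where Delta* is the largest grid value attaining
    the maximum accuracy — favouring fewer genes.
    """
    if data.labels is None:
        raise ValueError("dataset has no labels")
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    X = data.matrix
    y = data.labels.astype(np.int64)
    full = fit_nsc_arrays(X, y, delta=0.0, s0=s0)
    dmax = float(np.abs(full.scores).max())
    grid = np.linspace(0.0, dmax, grid_size) if grid_size > 1 else np.array([0.0])
    accs = []
    for delta in grid:
        correct = []
        sizes = []
        for round_ in plan.folds:
            for test_idx in round_:
                mask = np.ones(y.size, dtype=bool)
                mask[test_idx] = False
                model = fit_nsc_arrays(X[mask], y[mask], delta=float(delta), s0=s0)
                pred = model.predict(X[test_idx])
                correct.append(int((pred == y[test_idx]).sum()))
                sizes.append(len(test_idx))
        accs.append(measure_from_counts(correct, sizes))
    top = max(accs)
    i_star = max(i for i, a in enumerate(accs) if a == top)
    delta_star = float(grid[i_star])
    final = fit_nsc_arrays(X, y, delta=delta_star, s0=s0)
    active = [g for g, a in zip(data.gene_ids, final.active_genes) if a]
    return delta_star, active, float(top)
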