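# Methods

This note records the models implemented in `wrapsel`, the numerical and
design choices behind them, what the synthetic data generator does and does
not emulate, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Performance measure

The wrapper's objective is the mean accuracy of linear discriminant
analysis under repeated stratified k-fold cross-validation (default r=5
rounds of k=5 folds; r=k=10 runs through the same code path). Folds are
built by shuffling each class with a seeded generator and dealing members
cyclically to folds, with the dealing position carried over between
classes; this yields overall fold sizes differing by at most one *and*
per-class fold counts differing by at most one (for 14+18 samples and k=5:
sizes {7,7,6,6,6}, 2–3 positives per fold). Whether the original procedure
stratified its folds is not documented anywhere we could rely on;
stratification was chosen because at these class sizes an unstratified fold
can easily lose a class entirely.

One plan is created per selection run and reused for every subset
evaluation, so all subsets are compared on identical partitions. The
aggregate is the unweighted mean of the r·k fold accuracies (the pooled
correct fraction is also exposed; with near-equal folds they differ by
≤1e-2).

**Exact ties.** Each fold accuracy is a ratio of small integers, so the
measure is rational. The search computes it as an exact `Fraction` of the
integer per-fold correct counts; two subsets are "tied" iff their measures
are mathematically equal. This realises the exact-tie semantics that a
float bit-equality rule approximates, and is independent of summation
order.

## LDA

Class means, priors and the pooled covariance (class scatters summed,
divided by n−K) are the sample estimates; no hyper-parameters. If the
pooled covariance is singular at working precision — detected by a
vanishing Cholesky pivot (pivot² ≤ 1e-12 × the largest diagonal element),
which catches exact duplicates that a naive factorization slips past — a
relative ridge ε = 1e-8·trace(Σ)/d is added to the diagonal (escalating
tenfold if needed). The ridge keeps the classifier linear and
deterministic, unlike a pseudo-inverse. Exact discriminant ties predict
POSITIVE; this is documented and tested. Posteriors are computed in log
space and match direct equal-covariance Gaussian density evaluation to
1e-10 on random instances.

During the forward stage all candidates are evaluated in one vectorised
batch per fold (block covariance assembly + batched solves). This replaces
the original implementation's 8-way parallel candidate evaluation with a
schedule-free equivalent: results are bit-identical across runs by
construction, so tie sets are stable.

## Soft-margin linear SVM

The dual box-constrained QP is solved by sequential minimal optimization
with maximal-violating-pair working-set selection, stopping at a KKT
violation of 1e-8. The weight vector is the support-vector expansion
w = Σ αᵢyᵢxᵢ; the bias averages y − w·x over free support vectors
(0 < α < C), falling back to the midpoint of the KKT interval when none are
free. The solution carries its own certificates: duality gap, box and
complementarity residuals (all ≤1e-6 asserted in tests against an
independent generic QP solve). The penalty C is 1.0 by default and exposed
as configuration: the original tie-breaking used a MATLAB toolbox whose
effective penalty is not recoverable, so a neutral default was fixed once.
Note that duplicating every training sample preserves (w, b) only when no
slack is active; with active slack the penalty term doubles relative to
½‖w‖² and the optimum genuinely moves.

## Tie-breaking

When several candidate genes attain the identical measure, one SVM is
fitted on the current subset plus all tied candidates (for an addition) or
on the current subset (for a removal), and tied genes are ranked by |w| at
their own coordinate: additions keep the largest, removals drop the
smallest; exact |w| ties (e.g. bit-identical duplicated columns, whose
weights are equal by construction of the expansion) fall back to the lowest
column index. Fitting one joint SVM rather than one per candidate is the
cheaper of the two defensible readings; the per-candidate variant is
available (`joint=False`). An SVM failure degrades to the index rule with a
logged warning.

## The search

Strict improvement (>) is required in both stages; a ≥ variant for the
backward stage (`backward_allow_equal`) is available for ablations, and
terminates because each equal-measure removal strictly shrinks the subset.
The empty-set baseline measure is the majority-class rate, so the first
addition must beat majority voting. Removed genes are permanently excluded.
A `forward_only` flag disables the backward stage for ablation comparisons;
on tie-provoking fixtures the full algorithm never returns a larger subset
than the forward-only variant.

## Comparators

**SVM-RFE** refits on the surviving genes and eliminates the lowest-|w|
gene per round (one at a time by default; an `elimination_fraction` speeds
up large problems by dropping a fraction per round while >50 genes
survive). |w| ties are eliminated lowest-index-first, so fully
interchangeable genes are ranked in reverse column order.

**NSC** follows the shrunken-centroid construction: per-gene pooled
within-class SD s_i, offset s0 (default: median of s_i), standardization
factor m_k = √(1/n_k − 1/n), scores d_ik soft-thresholded by Δ, and a
standardized-distance discriminant with a −2·log π_k prior term. The
selection rule evaluates a grid of `grid_size` thresholds from 0 to
max|d_ik| by cross-validated accuracy and keeps the *largest* Δ attaining
the maximum (favouring fewer genes). The reference method computes its
threshold "adaptively" by means not documented precisely; this grid rule is
therefore labelled PAM-*style*, not PAM-exact.

## Interpretation layer

- **Mann-Whitney U**: exact permutation null when min(n₁,n₂) ≤ 8 and the
  pooled values are tie-free; otherwise the normal approximation with tie
  and continuity corrections (both via scipy behind the module surface).
  Default two-sided; `greater` and `less` are available — the one-sided
  direction depends on which class is passed first, so both sides are
  exposed rather than only `greater`.
- **Spearman ρ**: Pearson correlation of mid-ranks; zero rank variance
  yields NaN with a warning.
- **Chance-separation probability**: for an uninformative gene with
  distinct values the induced label arrangement is uniform; the probability
  that some cut point and orientation misclassify ≤ e samples is computed
  by exact integer dynamic programming over (ones placed, running min/max
  of the cut-error walk s(c) = c − 2·ones(c)), O(n³) states, and agrees
  with exhaustive enumeration for all n₁+n₂ ≤ 10. The any-of-G extension is
  1 − (1−p)^G under independence, evaluated via expm1/log1p so that p of
  order 1e-7 survives G ≈ 2×10⁴ without cancellation. Feasibility note: an
  arrangement attaining minimum threshold error exactly e exists iff
  e ≤ min(n₁,n₂) and 2e < n₁+n₂ — the balanced corner e = n₁ = n₂ is
  impossible because the error walk changes by ±1 per step and cannot have
  min_c s = max_c s = 0.
- **Depth-2 CART**: Gini impurity, candidate thresholds at midpoints of
  consecutive distinct values, no pruning (the depth cap replaces it),
  minimum leaf size 1; split ties prefer the lower column then the smaller
  threshold; leaf ties predict POSITIVE. Thresholds are rounded to one
  decimal only in the text rendering.

## Synthetic data

The generator emulates the *shape* of small two-class microarray studies:
tens of samples, 10²–10⁴ genes at a log2-like baseline (7.0 a.u.,
cosmetic), i.i.d. Gaussian noise with equal class covariance (matching
LDA's model, so parameter-recovery results are meaningful), a small planted
set whose class-mean difference is δ·noise_sd (i.e. standardized effect δ),
and optional bit-identical duplicate columns of planted genes to provoke
exact ties. It does **not** model probe effects, batch structure,
heteroscedastic intensity noise, or gene-gene correlation beyond exact
duplication — so passing tests demonstrate algorithmic correctness and
calibration under the idealised model, not robustness to real microarray
artifacts. One seed drives generation; the label vector is laid out as
n_pos positives then n_neg negatives and the sample order shuffled from the
same stream.

A separate helper plants a single-gene arrangement whose minimum
threshold error is exactly e (verified internally by the sweep), for
studying the near-perfect-separator scenario.

## Problem sizes used in the shipped studies

The recovery study in `scripts/acceptance.py` and the end-to-end tests uses
14+18 samples, 1000 genes, three planted genes at δ=1.5, 5×5 cv, C=1, ten
seeds; the null calibration uses 16+16 samples, 100 genes, ten seeds. At
δ=1.5 a planted gene's population single-gene accuracy is Φ(0.75) ≈ 0.77
while the best of ~1000 null genes typically scores 0.80–0.83 under
32-sample cross-validation, so greedy subset recovery at this effect size
is only partial; the shipped numbers report the measured rates as they are.

## Known limitations

- Two classes only; no multi-class discriminants.
- No nested cross-validation for C or Δ (deliberate at these sample sizes:
  an inner resampling loop would leave almost no data).
- The wrapper's final measure is an optimistically biased estimate of
  generalization accuracy because the search maximizes it over subsets;
  the chance-separation statistics quantify one facet of that bias but no
  bias-corrected error estimate is provided.
- SMO is tuned for the small-n problems this package targets (tens to a
  few hundred samples); it is not a large-scale SVM.
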