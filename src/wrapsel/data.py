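"""Data model and plain-text I/O for two-class expression matrices.

The in-memory orientation is always samples x genes; series-matrix style files
(genes as rows) are transposed at read time.  No normalisation, scaling or
filtering is ever applied on read: values are used as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "LabeledDataset",
    "SelectionResult",
    "TraceStep",
    "DataFormatError",
    "read_expression_table",
    "write_expression_table",
    "attach_labels",
    "write_labels",
    "write_selection_report",
    "read_selection_report",
]


class DataFormatError(ValueError):
    """Raised when an on-disk matrix or labels file violates the format contract."""


@dataclass(frozen=True)
class LabeledDataset:
    """Expression matrix (samples x genes) with optional binary class labels.

    ``labels`` is an int8 vector with 1 = POSITIVE (e.g. disease) and
    0 = NEGATIVE (e.g. healthy), aligned with ``sample_ids``; ``None`` for a
    matrix read before labels are attached.
    """

    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise DataFormatError("expression matrix must be 2-dimensional")
        if m.shape[0] != len(self.sample_ids):
            raise DataFormatError(
                f"{m.shape[0]} matrix rows but {len(self.sample_ids)} sample ids"
            )
        if m.shape[1] != len(self.gene_ids):
            raise DataFormatError(
                f"{m.shape[1]} matrix columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataFormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample ids")
        if not np.isfinite(m).all():
            raise DataFormatError("matrix contains missing or non-finite values")
        if self.labels is not None:
            y = np.asarray(self.labels, dtype=np.int8)
            object.__setattr__(self, "labels", y)
            if y.shape != (m.shape[0],):
                raise DataFormatError("labels length does not match sample count")
            if not np.isin(y, (0, 1)).all():
                raise DataFormatError("labels must be 0/1")
            if (y == 1).sum() < 2 or (y == 0).sum() < 2:
                raise DataFormatError("each class needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return int((self.labels == 1).sum()), int((self.labels == 0).sum())

    def y_signed(self) -> np.ndarray:
        """Labels as +1 (POSITIVE) / -1 (NEGATIVE) for margin classifiers."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return np.where(self.labels == 1, 1.0, -1.0)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown gene id: {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "LabeledDataset":
        """Column subset in the requested order; labels unchanged."""
        idx = self.gene_index(gene_ids)
        return replace(
            self, matrix=self.matrix[:, idx], gene_ids=tuple(gene_ids)
        )


def subset_genes(data: LabeledDataset, gene_ids: Sequence[str]) -> LabeledDataset:
    return data.subset_genes(gene_ids)


def read_expression_table(path: str | Path, genes_as: str = "rows") -> LabeledDataset:
    """Read a tab-separated expression matrix.

    ``genes_as`` states the on-disk orientation ("rows" is the series-matrix
    convention); the result is always samples x genes with labels unset.
    """
    if genes_as not in ("rows", "columns"):
        raise ValueError("genes_as must be 'rows' or 'columns'")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataFormatError(f"{path}: empty expression table")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        cells = df[col].to_numpy(dtype=str)
        try:
            # numpy's str->float64 conversion round-trips '%.17g' output
            values[:, j] = cells.astype(np.float64)
        except ValueError:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise DataFormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at row {row!r}, "
                f"column {col!r}"
            ) from None
    row_ids = tuple(str(i) for i in df.index)
    col_ids = tuple(str(c) for c in df.columns)
    if genes_as == "rows":
        gene_ids, sample_ids, matrix = row_ids, col_ids, values.T
    else:
        gene_ids, sample_ids, matrix = col_ids, row_ids, values
    if len(set(gene_ids)) != len(gene_ids):
        raise DataFormatError(f"{path}: duplicate gene ids")
    return LabeledDataset(matrix=matrix, gene_ids=gene_ids, sample_ids=sample_ids)


def write_expression_table(
    data: LabeledDataset, path: str | Path, genes_as: str = "rows"
) -> None:
    """Write the matrix as TSV ('.' decimal, full double precision)."""
    if genes_as not in ("rows", "columns"):
        raise ValueError("genes_as must be 'rows' or 'columns'")
    if genes_as == "rows":
        df = pd.DataFrame(
            data.matrix.T, index=list(data.gene_ids), columns=list(data.sample_ids)
        )
    else:
        df = pd.DataFrame(
            data.matrix, index=list(data.sample_ids), columns=list(data.gene_ids)
        )
    df.to_csv(path, sep="\t", float_format="%.17g")


def attach_labels(
    data: LabeledDataset,
    labels_path: str | Path,
    class_map: Mapping[str, str] | None = None,
) -> LabeledDataset:
    """Attach labels from a two-column TSV (sample_id <tab> class name).

    Alignment is by sample id, not file order.  ``class_map`` maps class names
    to POSITIVE/NEGATIVE; by default the lexicographically first class name is
    POSITIVE (so FSHD < Healthy maps the disease class to POSITIVE).
    """
    raw: dict[str, str] = {}
    with open(labels_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(
                    f"{labels_path}:{ln}: expected 'sample_id<TAB>class'"
                )
            raw[parts[0]] = parts[1]
    classes = sorted(set(raw.values()))
    if class_map is None:
        if len(classes) != 2:
            raise DataFormatError(
                f"{labels_path}: need exactly 2 classes, found {classes}"
            )
        class_map = {classes[0]: POSITIVE, classes[1]: NEGATIVE}
    mapped = {}
    for sid, cls in raw.items():
        try:
            mapped[sid] = class_map[cls]
        except KeyError:
            raise DataFormatError(
                f"{labels_path}: class {cls!r} not in class map"
            ) from None
    if len(set(mapped.values())) > 2:
        raise DataFormatError(f"{labels_path}: more than 2 mapped classes")
    missing = [s for s in data.sample_ids if s not in mapped]
    if missing:
        raise DataFormatError(
            f"{labels_path}: samples missing from labels file: {missing}"
        )
    y = np.array(
        [1 if mapped[s] == POSITIVE else 0 for s in data.sample_ids], dtype=np.int8
    )
    return replace(data, labels=y)


def write_labels(
    data: LabeledDataset,
    path: str | Path,
    class_names: Mapping[str, str] | None = None,
) -> None:
    """Write labels TSV; ``class_names`` maps POSITIVE/NEGATIVE to display names."""
    if data.labels is None:
        raise ValueError("dataset has no labels")
    names = class_names or {POSITIVE: POSITIVE, NEGATIVE: NEGATIVE}
    with open(path, "w") as fh:
        for sid, lab in zip(data.sample_ids, data.labels):
            fh.write(f"{sid}\t{names[POSITIVE if lab == 1 else NEGATIVE]}\n")


@dataclass(frozen=True)
class TraceStep:
    kind: str  # "ADD" or "REMOVE"
    gene_id: str
    measure: float

    def __post_init__(self) -> None:
        if self.kind not in ("ADD", "REMOVE"):
            raise ValueError(f"bad step kind {self.kind!r}")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a wrapper search: accepted genes in acceptance order, the
    permanently excluded genes, the step trace, and the final measure."""

    accepted: tuple[str, ...]
    excluded: frozenset[str]
    trace: tuple[TraceStep, ...]
    final_measure: float
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.accepted) & set(self.excluded):
            raise ValueError("accepted and excluded sets overlap")
        last = None
        for step in self.trace:
            if last is not None and not step.measure > last:
                raise ValueError("trace measure must be strictly increasing")
            last = step.measure
        if self.trace and self.final_measure != self.trace[-1].measure:
            raise ValueError("final_measure must equal the last trace measure")


def write_selection_report(result: SelectionResult, path: str | Path) -> None:
    payload = {
        "accepted": list(result.accepted),
        "excluded": sorted(result.excluded),
        "trace": [
            {"kind": s.kind, "gene_id": s.gene_id, "measure": s.measure}
            for s in result.trace
        ],
        "final_measure": result.final_measure,
        "seed": result.seed,
        "config": result.config,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_selection_report(path: str | Path) -> SelectionResult:
    with open(path) as fh:
        payload = json.load(fh)
    return SelectionResult(
        accepted=tuple(payload["accepted"]),
        excluded=frozenset(payload["excluded"]),
        trace=tuple(
            TraceStep(s["kind"], s["gene_id"], s["measure"]) for s in payload["trace"]
        ),
        final_measure=payload["final_measure"],
        seed=payload["seed"],
        config=payload.get("config", {}),
    )
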