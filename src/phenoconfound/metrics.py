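"""Confusion-matrix algebra.

The central evidence object of the analysis is the class-ordered confusion
matrix of counts (rows = true class, columns = predicted) together with its
row-normalised probability view.  From it derive: per-class true positive
rates (the diagonal of the probability view), overall accuracy, the
multiclass-to-binary reduction for each diagnosis, the Matthews correlation
coefficient of that reduction, and the accuracy expected of a classifier that
draws labels from the empirical class prior.

Conventions (documented, fixed):
* MCC with any zero margin is defined as 0.
* The TPR of an empty row is *missing* (NaN), never imputed — down-sampled
  iterations always have full rows, so a missing TPR signals a protocol bug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "BinaryContingency",
    "tpr",
    "accuracy",
    "binarize",
    "mcc",
    "expected_random_accuracy",
]


@dataclass(frozen=True, eq=False)
class ConfusionMatrix:
    """Class-ordered count matrix with a row-normalised probability view."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) non-negative ints

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConfusionMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.counts, other.counts
        )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if counts.shape[0] != len(self.labels):
            raise ValueError("counts shape does not match number of labels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_records(cls, y_true, y_pred, labels: Sequence[str]) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(labels=labels, counts=counts)

    # -- views ---------------------------------------------------------------

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def empty_rows(self) -> tuple[str, ...]:
        return tuple(
            lab for lab, s in zip(self.labels, self.row_sums) if s == 0
        )

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalised counts; rows with no observations are all zero."""
        rs = self.row_sums.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.counts / rs[:, None]
        p[rs == 0] = 0.0
        return p

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot pool confusion matrices with different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    # -- serialisation -------------------------------------------------------

    def to_frame(self, probabilities: bool = False) -> pd.DataFrame:
        data = self.probabilities if probabilities else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path: str | Path, probabilities: bool = False) -> None:
        """TSV: header = predicted labels, first column = true labels."""
        self.to_frame(probabilities).to_csv(path, sep="\t", index_label="true")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        labels = tuple(str(c) for c in frame.columns)
        if tuple(str(i) for i in frame.index) != labels:
            raise ValueError("confusion TSV row labels do not match column labels")
        return cls(labels=labels, counts=frame.to_numpy())


@dataclass(frozen=True)
class BinaryContingency:
    """One-vs-rest reduction of a multiclass confusion matrix."""

    tp: int
    fp: int
    fn: int
    tn: int
    target_class: str = ""

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def tpr(cm: ConfusionMatrix, label: str) -> float:
    """True positive rate of one class; NaN (missing) for an empty row."""
    i = cm.index_of(label)
    row = cm.row_sums[i]
    if row == 0:
        return math.nan
    return float(cm.counts[i, i] / row)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def binarize(cm: ConfusionMatrix, target_class: str) -> BinaryContingency:
    """Reduce the multiclass matrix to a two-class table for one diagnosis."""
    i = cm.index_of(target_class)
    tp = int(cm.counts[i, i])
    fn = int(cm.row_sums[i]) - tp
    fp = int(cm.col_sums[i]) - tp
    tn = cm.total - tp - fn - fp
    return BinaryContingency(tp=tp, fp=fp, fn=fn, tn=tn, target_class=target_class)


def mcc(bc: BinaryContingency) -> float:
    """Matthews correlation coefficient; 0 if any margin is zero."""
    tp, fp, fn, tn = bc.tp, bc.fp, bc.fn, bc.tn
    if bc.total <= 0:
        raise ValueError("MCC undefined for an empty contingency table")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom2))


def expected_random_accuracy(class_sizes: Sequence[int]) -> float:
    """Accuracy of drawing predictions from the empirical class prior.

    Equals sum(p_i^2) for prior p_i = size_i / total — the chance-level
    baseline to which the classifier's accuracy is compared.
    """
    sizes = np.asarray(list(class_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("class_sizes must be non-empty")
    if np.any(sizes < 1):
        raise ValueError("class sizes must be >= 1")
    p = sizes / sizes.sum()
    return float(np.sum(p**2))
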