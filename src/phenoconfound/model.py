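"""Stand-in gestalt classifier.

The proprietary face-analysis network behind the original study is replaced
by a nearest-centroid Gaussian-kernel classifier over embedding vectors: each
syndrome model is the mean embedding of its training cohort, and a case's
per-class similarity score is

    score_c  ∝  exp(−‖x − μ_c‖² / (2 σ²)),      normalised to sum to 1,

with σ the pooled within-class standard deviation estimated from the training
residuals.  The classifier exposes the scikit-learn estimator API, so it
composes with pipelines and model selection; it is also pluggable — any
scorer producing per-class scores summing to one can stand behind the same
evaluation protocol (so real gestalt scores could be injected later).

Evaluation is leave-one-out: each record is scored by a model whose *own*
class centroid was recomputed without that record; the other class centroids
(and the pooled σ) are left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import CohortManifest, PatientRecord
from .metrics import ConfusionMatrix

__all__ = [
    "GestaltClassifier",
    "ScoreVector",
    "fit_model",
    "score_case",
    "loo_confusion",
    "binary_auroc",
    "auroc_from_scores",
]

SD_FLOOR = 1e-9  # keeps scores defined when training cohorts are duplicates


@dataclass(frozen=True)
class ScoreVector:
    """Per-class similarity scores for one case (non-negative, sum to 1)."""

    case_id: str
    labels: tuple[str, ...]
    scores: tuple[float, ...]
    predicted: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.scores))


class GestaltClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid Gaussian-kernel classifier over embeddings.

    Parameters
    ----------
    sd_floor : float
        Lower bound on the pooled within-class SD; a degenerate (all
        duplicate) training set yields this floor, at which point prediction
        reduces to the nearest centroid.

    Attributes
    ----------
    classes_ : ndarray of shape (k,)
        Class labels in lexicographic order.
    centroids_ : ndarray of shape (k, d)
        Mean embedding per class.
    pooled_within_sd_ : float
        sqrt(mean squared residual norm / d) over all training records.
    """

    def __init__(self, sd_floor: float = SD_FLOOR):
        self.sd_floor = sd_floor

    def fit(self, X, y) -> "GestaltClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d array of embeddings")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        classes, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx, minlength=len(classes))
        for label, n in zip(classes, counts):
            if n < 2:
                raise ValueError(
                    f"class {label!r} has {n} record(s); >= 2 required to fit"
                )
        k, d = len(classes), X.shape[1]
        centroids = np.zeros((k, d))
        for c in range(k):
            centroids[c] = X[y_idx == c].mean(axis=0)
        residuals = X - centroids[y_idx]
        sd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1)) / d))
        self.classes_ = classes
        self.class_counts_ = counts
        self.centroids_ = centroids
        self.pooled_within_sd_ = max(sd, self.sd_floor)
        self.n_features_in_ = d
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"embedding dimension {X.shape[1]} != model dimension "
                f"{self.n_features_in_}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Log-kernel scores −‖x−μ_c‖²/(2σ²), shape (n, k)."""
        X = self._check_X(X)
        d2 = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return -d2 / (2.0 * self.pooled_within_sd_**2)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X) -> np.ndarray:
        # argmax takes the first maximal index; classes_ is sorted, so ties
        # resolve to the lexicographically smallest label.
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# record-level wrappers
# ---------------------------------------------------------------------------


def fit_model(records: list[PatientRecord] | CohortManifest) -> GestaltClassifier:
    """Fit a gestalt model from patient records (each class needs >= 2)."""
    if isinstance(records, CohortManifest):
        X, y = records.to_Xy()
    else:
        X = np.array([r.embedding for r in records], dtype=float)
        y = np.array([r.syndrome for r in records], dtype=object)
    return GestaltClassifier().fit(X, y)


def score_case(record: PatientRecord, model: GestaltClassifier) -> ScoreVector:
    """Per-class similarity scores for one record under a fitted model."""
    proba = model.predict_proba(np.asarray(record.embedding, dtype=float))[0]
    labels = tuple(str(c) for c in model.classes_)
    predicted = labels[int(np.argmax(proba))]
    return ScoreVector(
        case_id=record.case_id,
        labels=labels,
        scores=tuple(float(p) for p in proba),
        predicted=predicted,
    )


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------


def _loo_logits(X: np.ndarray, y: np.ndarray) -> tuple[GestaltClassifier, np.ndarray]:
    """Log-kernel scores with each record held out of its own centroid."""
    clf = GestaltClassifier().fit(X, y)
    logits = clf.decision_function(X)
    class_index = {label: i for i, label in enumerate(clf.classes_)}
    sigma2 = 2.0 * clf.pooled_within_sd_**2
    for i in range(X.shape[0]):
        c = class_index[y[i]]
        n_c = clf.class_counts_[c]
        mu_held_out = (n_c * clf.centroids_[c] - X[i]) / (n_c - 1)
        logits[i, c] = -np.sum((X[i] - mu_held_out) ** 2) / sigma2
    return clf, logits


def loo_confusion(manifest: CohortManifest) -> ConfusionMatrix:
    """Leave-one-out confusion matrix over a manifest's records.

    Rows are true classes, columns predicted; row order follows the
    manifest's declared class labels.
    """
    X, y = manifest.to_Xy()
    clf, logits = _loo_logits(X, y)
    predicted = clf.classes_[np.argmax(logits, axis=1)]
    return ConfusionMatrix.from_records(
        y_true=y, y_pred=predicted, labels=manifest.class_labels
    )


def auroc_from_scores(scores_a, scores_b) -> float:
    """AUROC as the Mann–Whitney concordance probability (ties count 1/2)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    u = mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(u / (a.size * b.size))


def binary_auroc(
    cohort_a: list[PatientRecord], cohort_b: list[PatientRecord]
) -> float:
    """AUROC of the two-cohort discriminant score_a − score_b, LOO-evaluated.

    The discriminant is oriented canonically (by a deterministic cohort key)
    rather than by argument order, so ``auroc(a, b) + auroc(b, a) == 1``
    holds exactly.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("each cohort needs >= 2 records")

    def cohort_key(records: list[PatientRecord]):
        return tuple(sorted((r.syndrome, r.case_id) for r in records))

    if cohort_key(cohort_b) < cohort_key(cohort_a):
        return 1.0 - binary_auroc(cohort_b, cohort_a)
    records = list(cohort_a) + list(cohort_b)
    X = np.array([r.embedding for r in records], dtype=float)
    y = np.array(["a"] * len(cohort_a) + ["b"] * len(cohort_b), dtype=object)
    _, logits = _loo_logits(X, y)
    proba = softmax(logits, axis=1)
    stats = proba[:, 0] - proba[:, 1]  # classes_ sorted: column 0 is "a"
    return auroc_from_scores(stats[: len(cohort_a)], stats[len(cohort_a) :])
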