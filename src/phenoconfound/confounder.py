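"""Confounder-testing framework.

The core procedure for deciding whether a covariate (sex, ethnicity, cohort
size) confounds the apparent distinguishability of syndrome cohorts:

1.  *Down-sampling*: to remove cohort size as a covariate, every class is
    sampled down to the greatest common size available after a covariate
    filter (e.g. males only).
2.  *Repeated experiments*: each setting is run for several iterations
    (default 5) with independent random down-samples; per-iteration
    leave-one-out confusion matrices yield per-class TPRs and one-vs-rest
    MCCs, aggregated as means and sample SDs.
3.  *The ΔMCC / 2·SD rule*: a covariate-restricted ("homogeneous")
    experiment is compared to an unrestricted ("mixed") control at the same
    sample size.  Per class, the difference of mean MCCs is normalised by
    the sample SD of the control iterations' MCCs; the covariate is flagged
    as having a significant effect only when |ΔMCC / SD| exceeds 2
    (strictly — a difference *within* two control SDs is regarded as no
    effect).
4.  *Cohort-size sweep*: evenly sized subsets (default 10..40) quantify how
    TPR grows with cohort size; per-iteration TPRs are fitted against size
    by ordinary least squares and the slope tested against zero.

Seed discipline: iteration i's subsample depends only on
(master_seed, filter, sample_size, i), so any single iteration can be
reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import linregress

from ._seeding import derive_rng
from .cohort import CohortManifest
from .metrics import ConfusionMatrix, accuracy, binarize, mcc, tpr
from .model import loo_confusion

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "ConfounderReport",
    "ClassAssessment",
    "SizeSweepResult",
    "greatest_common_size",
    "run_repeated_experiment",
    "assess_confounder",
    "size_sweep",
    "fit_tpr_trend",
]

logger = logging.getLogger(__name__)

ConfusionFn = Callable[[CohortManifest], ConfusionMatrix]

# a filter is {covariate: value} applied to all classes, or {class: {cov: val}}
CovariateFilter = Mapping[str, object] | None


def _normalize_filters(
    filters: CovariateFilter, class_labels: Sequence[str]
) -> dict[str, dict[str, str]]:
    """Per-class {covariate: value} dicts; empty dict = no filter (mixed)."""
    per_class: dict[str, dict[str, str]] = {c: {} for c in class_labels}
    if not filters:
        return per_class
    values = list(filters.values())
    if all(isinstance(v, Mapping) for v in values):
        for cls, f in filters.items():  # type: ignore[union-attr]
            if cls not in per_class:
                raise KeyError(f"filter names unknown class {cls!r}")
            per_class[cls] = {str(k): str(v) for k, v in f.items()}
    else:
        shared = {str(k): str(v) for k, v in filters.items()}
        for cls in per_class:
            per_class[cls] = dict(shared)
    return per_class


def _filtered_pools(
    manifest: CohortManifest, filters: CovariateFilter
) -> dict[str, list]:
    per_class = _normalize_filters(filters, manifest.class_labels)
    groups = manifest.by_class()
    pools: dict[str, list] = {}
    for cls, records in groups.items():
        f = per_class[cls]
        for cov in f:
            if cov not in ("sex", "ethnicity", "treated"):
                raise KeyError(f"unknown covariate {cov!r} in filter")
        pools[cls] = [
            r for r in records if all(r.covariate(k) == v for k, v in f.items())
        ]
    return pools


def greatest_common_size(
    manifest: CohortManifest, covariate_filter: CovariateFilter = None
) -> int:
    """Largest per-class sample size every class can supply after filtering.

    Raises if any class has no passing record (no experiment is possible).
    """
    pools = _filtered_pools(manifest, covariate_filter)
    for cls, pool in pools.items():
        if len(pool) == 0:
            raise ValueError(
                f"class {cls!r} has no records passing filter "
                f"{covariate_filter!r}; no experiment possible"
            )
    return min(len(pool) for pool in pools.values())


@dataclass(frozen=True)
class ExperimentSpec:
    """One down-sampled repeated experiment.

    ``cohort_filters`` is either a single {covariate: value} mapping applied
    to every class, a per-class mapping of such mappings, or None for the
    mixed (unfiltered) control.
    """

    sample_size: int
    cohort_filters: CovariateFilter = None
    n_iterations: int = 5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2 (LOO needs 2 per class)")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2 (SD needs >= 2 values)")

    def filter_key(self) -> str:
        if not self.cohort_filters:
            return "mixed"
        return repr(sorted((str(k), repr(v)) for k, v in self.cohort_filters.items()))


@dataclass(frozen=True, eq=False)
class ExperimentResult:
    """Per-class TPR/MCC means and sample SDs over resampling iterations."""

    labels: tuple[str, ...]
    sample_size: int
    n_iterations: int
    tpr_values: np.ndarray  # (k, n_iterations)
    mcc_values: np.ndarray  # (k, n_iterations)
    accuracy_values: np.ndarray  # (n_iterations,)
    confusions: tuple[ConfusionMatrix, ...]
    spec: ExperimentSpec | None = field(default=None, compare=False)

    @property
    def mean_tpr(self) -> np.ndarray:
        return self.tpr_values.mean(axis=1)

    @property
    def sd_tpr(self) -> np.ndarray:
        return self.tpr_values.std(axis=1, ddof=1)

    @property
    def mean_mcc(self) -> np.ndarray:
        return self.mcc_values.mean(axis=1)

    @property
    def sd_mcc(self) -> np.ndarray:
        return self.mcc_values.std(axis=1, ddof=1)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy_values.mean())

    def class_mean_mcc(self, label: str) -> float:
        return float(self.mean_mcc[self.labels.index(label)])


def run_repeated_experiment(
    manifest: CohortManifest,
    spec: ExperimentSpec,
    confusion_fn: ConfusionFn = loo_confusion,
) -> ExperimentResult:
    """Run ``spec.n_iterations`` down-sampled LOO evaluations and aggregate.

    Each iteration samples ``spec.sample_size`` records per class without
    replacement from the filtered pools (independent redraws across
    iterations, so overlap between iterations is allowed), evaluates the
    leave-one-out confusion matrix, and records per-class TPRs and
    one-vs-rest MCCs.  Deterministic given ``spec.master_seed``.
    """
    pools = _filtered_pools(manifest, spec.cohort_filters)
    for cls, pool in pools.items():
        if len(pool) < spec.sample_size:
            raise ValueError(
                f"class {cls!r} has only {len(pool)} record(s) passing filter "
                f"{spec.cohort_filters!r}; sample_size {spec.sample_size} "
                "exceeds the greatest common size"
            )

    labels = tuple(manifest.class_labels)
    k = len(labels)
    tpr_values = np.zeros((k, spec.n_iterations))
    mcc_values = np.zeros((k, spec.n_iterations))
    accuracy_values = np.zeros(spec.n_iterations)
    confusions: list[ConfusionMatrix] = []

    for i in range(spec.n_iterations):
        rng = derive_rng(
            spec.master_seed, "experiment-iteration", spec.filter_key(),
            spec.sample_size, i,
        )
        sampled = []
        for cls in labels:
            pool = pools[cls]
            idx = rng.choice(len(pool), size=spec.sample_size, replace=False)
            sampled.extend(pool[j] for j in sorted(idx))
        sub = manifest.subset(sampled)
        cm = confusion_fn(sub)
        confusions.append(cm)
        accuracy_values[i] = accuracy(cm)
        for c, cls in enumerate(labels):
            tpr_values[c, i] = tpr(cm, cls)
            mcc_values[c, i] = mcc(binarize(cm, cls))
        logger.info(
            "iteration %d: filter=%s size=%d accuracy=%.4f",
            i, spec.filter_key(), spec.sample_size, accuracy_values[i],
        )

    return ExperimentResult(
        labels=labels,
        sample_size=spec.sample_size,
        n_iterations=spec.n_iterations,
        tpr_values=tpr_values,
        mcc_values=mcc_values,
        accuracy_values=accuracy_values,
        confusions=tuple(confusions),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# the ΔMCC / 2·SD rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassAssessment:
    """Per-class outcome of the confounder comparison."""

    label: str
    mcc_confounder_mean: float
    mcc_control_mean: float
    delta_mcc: float
    sd_control: float
    ratio: float | None  # None when the control SD is zero (undefined)
    flagged: bool | None  # None = indeterminate (undefined ratio)


@dataclass(frozen=True)
class ConfounderReport:
    """Table-1-style report: ΔMCC normalised by the control SD, per class."""

    assessments: tuple[ClassAssessment, ...]
    sample_size: int
    threshold: float = 2.0

    def __iter__(self):
        return iter(self.assessments)

    def flagged_classes(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.assessments if a.flagged)

    def for_class(self, label: str) -> ClassAssessment:
        for a in self.assessments:
            if a.label == label:
                return a
        raise KeyError(f"unknown class label {label!r}")


def assess_confounder(
    result_confounder: ExperimentResult,
    result_control: ExperimentResult,
    threshold: float = 2.0,
) -> ConfounderReport:
    """Apply the ΔMCC / 2·SD decision rule per class.

    ``delta = mean MCC(confounder) − mean MCC(control)`` is normalised by the
    sample SD of the control iterations' MCCs; a class is flagged only when
    ``|ratio| > threshold`` strictly.  A zero control SD leaves the ratio
    undefined and the flag indeterminate.
    """
    if result_confounder.labels != result_control.labels:
        raise ValueError("experiments cover different class labels")
    if result_confounder.sample_size != result_control.sample_size:
        raise ValueError(
            "experiments used different sample sizes "
            f"({result_confounder.sample_size} vs {result_control.sample_size}); "
            "the comparison requires equal down-sampling"
        )
    assessments = []
    for c, label in enumerate(result_control.labels):
        m_conf = float(result_confounder.mean_mcc[c])
        m_ctrl = float(result_control.mean_mcc[c])
        delta = m_conf - m_ctrl
        sd = float(result_control.sd_mcc[c])
        if sd == 0.0:
            ratio: float | None = None
            flagged: bool | None = None
        else:
            ratio = delta / sd
            flagged = abs(ratio) > threshold
        assessments.append(
            ClassAssessment(
                label=label,
                mcc_confounder_mean=m_conf,
                mcc_control_mean=m_ctrl,
                delta_mcc=delta,
                sd_control=sd,
                ratio=ratio,
                flagged=flagged,
            )
        )
    return ConfounderReport(
        assessments=tuple(assessments),
        sample_size=result_control.sample_size,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# cohort-size sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r: float
    p_value: float


@dataclass(frozen=True, eq=False)
class SizeSweepResult:
    """TPR-vs-cohort-size sweep with per-class linear fits."""

    sizes: tuple[int, ...]
    labels: tuple[str, ...]
    tpr_values: np.ndarray  # (k, n_sizes, n_iterations)
    fits: Mapping[str, TrendFit]
    results: tuple[ExperimentResult, ...]


def fit_tpr_trend(sizes: Sequence[float], tpr_values: Sequence[float]) -> TrendFit:
    """OLS fit of TPR against cohort size (all per-iteration points)."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(tpr_values, dtype=float)
    if x.size != y.size:
        raise ValueError("sizes and TPR values have different lengths")
    if x.size < 3:
        raise ValueError("linear fit refused with fewer than 3 points")
    fit = linregress(x, y)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
    )


def size_sweep(
    manifest: CohortManifest,
    sizes: Sequence[int] = (10, 20, 30, 40),
    n_iterations: int = 5,
    master_seed: int = 0,
    cohort_filters: CovariateFilter = None,
    confusion_fn: ConfusionFn = loo_confusion,
) -> SizeSweepResult:
    """Repeat the experiment at each cohort size and fit TPR against size.

    The fit uses every per-iteration TPR value (not iteration means), one
    ordinary-least-squares line per class, with a two-sided p-value for
    slope = 0.
    """
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) < 2 or any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be >= 2 strictly increasing values")
    gcs = greatest_common_size(manifest, cohort_filters)
    if max(sizes) > gcs:
        raise ValueError(
            f"max size {max(sizes)} exceeds the greatest common size {gcs}"
        )
    results = []
    for size in sizes:
        spec = ExperimentSpec(
            sample_size=size,
            cohort_filters=cohort_filters,
            n_iterations=n_iterations,
            master_seed=master_seed,
        )
        results.append(run_repeated_experiment(manifest, spec, confusion_fn))

    labels = tuple(manifest.class_labels)
    k = len(labels)
    tpr_values = np.stack([r.tpr_values for r in results], axis=1)  # (k, s, i)
    x = np.repeat(np.asarray(sizes, dtype=float), n_iterations)
    fits = {
        label: fit_tpr_trend(x, tpr_values[c].ravel())
        for c, label in enumerate(labels)
    }
    return SizeSweepResult(
        sizes=sizes,
        labels=labels,
        tpr_values=tpr_values,
        fits=fits,
        results=tuple(results),
    )
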