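"""Differential-diagnosis ranking against a large syndrome-model library.

Clinical gestalt-matching services rank each uploaded case against a library
of roughly 300 syndrome models and return the top 30 differential diagnoses
(DDx).  This module emulates that analysis: study-class models are fitted
from the manifest, background models are seeded random centroids placed at a
configurable separation, every case receives a full deterministic ranking,
and per-cohort statistics report how often a syndrome appears within the top
K ranks and at rank 1.  A non-correct syndrome appearing in more than 10% of
a cohort's top-30 lists is flagged as phenotypically similar.

Clinically grouped diagnoses (e.g. the two mucopolysaccharidosis subtypes
forming one "MPS" phenotypic series) can be merged through a label map
before frequencies are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax

from ._seeding import derive_rng
from .cohort import CohortManifest, PatientRecord
from .model import GestaltClassifier, fit_model

__all__ = [
    "ModelLibrary",
    "RankedDDx",
    "SimilarityFlag",
    "build_library",
    "rank_case",
    "topk_frequency",
    "similarity_flags",
]


@dataclass(frozen=True, eq=False)
class ModelLibrary:
    """Ordered syndrome models: one centroid per label, shared kernel SD."""

    labels: tuple[str, ...]
    centroids: np.ndarray  # (m, d)
    sd: float

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in model library")
        if self.centroids.shape[0] != len(self.labels):
            raise ValueError("one centroid required per label")
        if self.sd <= 0:
            raise ValueError("kernel SD must be positive")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RankedDDx:
    """Full deterministic ranking of one case against the library."""

    case_id: str
    ranking: tuple[tuple[str, float], ...]  # (syndrome, score), descending

    def rank_of(self, syndrome: str) -> int | None:
        """1-based rank of ``syndrome``, or None if absent."""
        for i, (label, _) in enumerate(self.ranking, start=1):
            if label == syndrome:
                return i
        return None

    def top(self, k: int) -> tuple[str, ...]:
        return tuple(label for label, _ in self.ranking[:k])


def build_library(
    manifest: CohortManifest,
    n_background: int = 295,
    seed: int = 0,
    background_separation: float = 8.0,
) -> ModelLibrary:
    """Study-class models plus seeded random background centroids.

    Background centroids are placed at radius
    ``background_separation * pooled_sd`` from the centre of the study
    centroids, in seeded random directions — emulating the large library of
    unrelated syndrome models a clinical service ranks against.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    clf: GestaltClassifier = fit_model(manifest)
    study_labels = tuple(str(c) for c in clf.classes_)
    sd = clf.pooled_within_sd_
    centre = clf.centroids_.mean(axis=0)
    rng = derive_rng(seed, "ddx-background")
    dim = clf.n_features_in_
    bg_centroids = np.zeros((n_background, dim))
    for j in range(n_background):
        v = rng.standard_normal(dim)
        bg_centroids[j] = centre + background_separation * sd * v / np.linalg.norm(v)
    bg_labels = tuple(f"BG-{j + 1:04d}" for j in range(n_background))
    return ModelLibrary(
        labels=study_labels + bg_labels,
        centroids=np.vstack([clf.centroids_, bg_centroids]),
        sd=sd,
    )


def rank_case(record: PatientRecord, library: ModelLibrary) -> RankedDDx:
    """Score one case against every library model; ties rank lexicographically."""
    x = np.asarray(record.embedding, dtype=float)
    if x.shape[0] != library.centroids.shape[1]:
        raise ValueError(
            f"record {record.case_id!r}: embedding dimension {x.shape[0]} != "
            f"library dimension {library.centroids.shape[1]}"
        )
    d2 = ((library.centroids - x) ** 2).sum(axis=1)
    scores = softmax(-d2 / (2.0 * library.sd**2))
    order = sorted(
        range(len(library)), key=lambda i: (-scores[i], library.labels[i])
    )
    return RankedDDx(
        case_id=record.case_id,
        ranking=tuple((library.labels[i], float(scores[i])) for i in order),
    )


def _map_label(label: str, label_map: Mapping[str, str] | None) -> str:
    if label_map is None:
        return label
    return label_map.get(label, label)


def topk_frequency(
    rankings: Sequence[RankedDDx],
    syndrome: str,
    k: int,
    label_map: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """(fraction of cases with ``syndrome`` in the top k, fraction at rank 1).

    ``label_map`` merges phenotypic-series labels before counting (a mapped
    syndrome occupies the best rank of any of its members).
    """
    if not rankings:
        raise ValueError("rankings must be non-empty")
    if k < 1 or k > len(rankings[0].ranking):
        raise ValueError(f"k={k} outside the library size")
    known = {_map_label(label, label_map) for label, _ in rankings[0].ranking}
    target = _map_label(syndrome, label_map)
    if target not in known:
        raise KeyError(f"unknown syndrome label {syndrome!r}")
    n_topk = 0
    n_rank1 = 0
    for r in rankings:
        top_labels = [_map_label(label, label_map) for label in r.top(k)]
        if target in top_labels:
            n_topk += 1
        if top_labels and top_labels[0] == target:
            n_rank1 += 1
    return n_topk / len(rankings), n_rank1 / len(rankings)


@dataclass(frozen=True)
class SimilarityFlag:
    cohort: str
    syndrome: str
    frequency: float
    flagged: bool


def similarity_flags(
    rankings_by_cohort: Mapping[str, Sequence[RankedDDx]],
    k: int = 30,
    threshold: float = 0.10,
    label_map: Mapping[str, str] | None = None,
    candidate_labels: Sequence[str] | None = None,
) -> tuple[SimilarityFlag, ...]:
    """Flag non-correct syndromes appearing above ``threshold`` in the top k.

    The flag is strict (``frequency > threshold``): with ~300 models to
    choose from, a wrong diagnosis recurring in more than 10% of a cohort's
    top-30 lists indicates phenotypic similarity.  ``candidate_labels``
    restricts the syndromes examined (default: every study-cohort label).
    """
    flags: list[SimilarityFlag] = []
    cohort_labels = [_map_label(c, label_map) for c in rankings_by_cohort]
    for cohort, rankings in rankings_by_cohort.items():
        correct = _map_label(cohort, label_map)
        if candidate_labels is None:
            candidates = cohort_labels
        else:
            candidates = [_map_label(c, label_map) for c in candidate_labels]
        seen: set[str] = set()
        for candidate in candidates:
            if candidate == correct or candidate in seen:
                continue
            seen.add(candidate)
            freq, _ = topk_frequency(rankings, candidate, k, label_map)
            flags.append(
                SimilarityFlag(
                    cohort=correct,
                    syndrome=candidate,
                    frequency=freq,
                    flagged=freq > threshold,
                )
            )
    return tuple(flags)
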