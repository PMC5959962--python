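"""Phenotype-similarity dendrogram from confusion probabilities.

Classes that a classifier frequently mistakes for one another are, by that
classifier's lights, phenotypically similar.  The distance between two
classes is defined as one minus the symmetrised confusion probability,

    d(i, j) = 1 − (P[i][j] + P[j][i]) / 2,

the minimal monotone choice mapping high mutual confusion to small distance
(the transform is swappable).  The dendrogram is average-linkage (UPGMA)
agglomerative clustering of that distance matrix, which yields an ultrametric
tree; node heights follow the half-distance convention (a merge at cluster
distance d sits at height d/2, so leaf-to-leaf path length equals d).

UPGMA is implemented here directly — O(k^3), fine for the handful of
syndrome classes involved — with a deterministic tie-break (the pair whose
label-sorted names come first), so identical inputs always give identical
trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ConfusionMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Merge",
    "confusion_to_distance",
    "upgma",
    "to_newick",
    "write_newick",
]


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal, entries in [0,1]."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0) or np.any(d > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, sep="\t", index_label="class"
        )


@dataclass(frozen=True)
class Merge:
    node_a: int
    node_b: int
    height: float
    new_node_id: int


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree over classes; leaves are ids 0..k−1 in label order."""

    leaf_labels: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        k = len(self.leaf_labels)
        if self.merges and len(self.merges) != k - 1:
            raise ValueError("a dendrogram over k leaves needs k−1 merges")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def node_height(self, node_id: int) -> float:
        if node_id < len(self.leaf_labels):
            return 0.0
        return self.merges[node_id - len(self.leaf_labels)].height

    def leaves_under(self, node_id: int) -> frozenset[str]:
        """Set of leaf labels in the clade rooted at ``node_id``."""
        k = len(self.leaf_labels)
        if node_id < k:
            return frozenset({self.leaf_labels[node_id]})
        m = self.merges[node_id - k]
        return self.leaves_under(m.node_a) | self.leaves_under(m.node_b)

    def clades(self) -> tuple[frozenset[str], ...]:
        k = len(self.leaf_labels)
        return tuple(self.leaves_under(k + i) for i in range(len(self.merges)))

    def has_clade(self, labels) -> bool:
        return frozenset(labels) in set(self.clades())


def confusion_to_distance(cm: ConfusionMatrix) -> DistanceMatrix:
    """d(i,j) = 1 − symmetrised confusion probability; error on empty rows."""
    if len(cm.labels) < 2:
        raise ValueError("need >= 2 classes for a distance matrix")
    if cm.empty_rows:
        raise ValueError(
            f"confusion matrix has empty rows {cm.empty_rows}; distance undefined"
        )
    p = cm.probabilities
    d = 1.0 - (p + p.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=cm.labels, d=np.clip(d, 0.0, 1.0))


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering (deterministic tie-break).

    At each step the two active clusters at the smallest average leaf-pair
    distance are merged at height d/2; among equal distances, the pair whose
    (lexicographically smallest member label, then partner label) sorts
    first is merged first.
    """
    k = len(dm.labels)
    # cluster id -> (member leaf indices, min member label)
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    min_label: dict[int, str] = {i: dm.labels[i] for i in range(k)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            dist[(i, j)] = float(dm.d[i, j])

    merges: list[Merge] = []
    next_id = k
    while len(members) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for (i, j), dij in dist.items():
            la, lb = sorted((min_label[i], min_label[j]))
            key = (dij, la, lb, i, j)
            if best is None or key < best:
                best = key
        assert best is not None
        dij, _, _, i, j = best
        a, b = (i, j) if min_label[i] <= min_label[j] else (j, i)
        merges.append(Merge(node_a=a, node_b=b, height=dij / 2.0, new_node_id=next_id))

        merged = members[i] + members[j]
        new_min = min(min_label[i], min_label[j])
        # average linkage over all leaf pairs = size-weighted combination
        ni, nj = len(members[i]), len(members[j])
        new_dist: dict[tuple[int, int], float] = {}
        for other in members:
            if other in (i, j):
                continue
            dio = dist[tuple(sorted((i, other)))]
            djo = dist[tuple(sorted((j, other)))]
            new_dist[(other, next_id)] = (ni * dio + nj * djo) / (ni + nj)
        for key_ in [key_ for key_ in dist if i in key_ or j in key_]:
            del dist[key_]
        del members[i], members[j], min_label[i], min_label[j]
        members[next_id] = merged
        min_label[next_id] = new_min
        dist.update(new_dist)
        next_id += 1

    return Dendrogram(leaf_labels=dm.labels, merges=tuple(merges))


def _newick_label(label: str) -> str:
    if any(ch in label for ch in " \t(),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths (ultrametric, half-distance heights)."""
    k = len(dendrogram.leaf_labels)
    if k == 1 and not dendrogram.merges:
        return _newick_label(dendrogram.leaf_labels[0]) + ";"

    def render(node_id: int, parent_height: float) -> str:
        branch = parent_height - dendrogram.node_height(node_id)
        if node_id < k:
            return f"{_newick_label(dendrogram.leaf_labels[node_id])}:{branch:g}"
        m = dendrogram.merges[node_id - k]
        inner = f"({render(m.node_a, m.height)},{render(m.node_b, m.height)})"
        if branch == 0.0 and node_id == dendrogram.merges[-1].new_node_id:
            return inner
        return f"{inner}:{branch:g}"

    root = dendrogram.merges[-1]
    return (
        f"({render(root.node_a, root.height)},{render(root.node_b, root.height)});"
    )


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(dendrogram) + "\n", encoding="utf-8")
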