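"""Cohort containers and manifest I/O.

A cohort manifest is one row per patient photo-equivalent: a syndrome label,
demographic covariates (sex, ethnicity, age, treatment status), an opaque
annotation field and a fixed-length numeric embedding standing in for the
facial-photo representation.

Manifest file dialect (one dialect only, to avoid parser ambiguity): UTF-8
CSV with a header row, preceded by a single ``#class_labels=...`` comment
line preserving class order; the embedding is serialised as a semicolon-joined
numeric list in one column, at full (round-trippable) precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "ETHNICITIES",
    "MANIFEST_COLUMNS",
    "PatientRecord",
    "CohortManifest",
    "ManifestError",
    "read_manifest",
    "write_manifest",
]

SEXES = ("male", "female", "unknown")
ETHNICITIES = ("EUR", "AFR", "other", "unknown")
TREATED = ("yes", "no", "unknown")

MANIFEST_COLUMNS = (
    "case_id",
    "syndrome",
    "sex",
    "ethnicity",
    "age",
    "treated",
    "annotations",
    "embedding",
)


class ManifestError(ValueError):
    """Raised for malformed manifests; the message names the offending row."""


@dataclass(frozen=True)
class PatientRecord:
    """One photo-equivalent sample."""

    case_id: str
    syndrome: str
    sex: str
    ethnicity: str
    age: float
    treated: str
    embedding: tuple[float, ...]
    annotations: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"record {self.case_id!r}: unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"record {self.case_id!r}: unknown ethnicity {self.ethnicity!r}"
            )
        if self.treated not in TREATED:
            raise ValueError(
                f"record {self.case_id!r}: unknown treatment status {self.treated!r}"
            )
        if self.age < 0:
            raise ValueError(f"record {self.case_id!r}: negative age")

    def covariate(self, name: str) -> str:
        if name not in ("sex", "ethnicity", "treated"):
            raise KeyError(f"unknown covariate {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class CohortManifest:
    """An ordered collection of patient records with declared class labels.

    ``provenance`` records how the manifest came to be: a
    :class:`~phenoconfound.simulate.SimulationConfig` for simulated cohorts,
    the string ``"external"`` for manifests read from disk.
    """

    records: tuple[PatientRecord, ...]
    class_labels: tuple[str, ...]
    embed_dim: int
    # provenance is bookkeeping, not data: excluded from equality so that a
    # written-then-read manifest compares equal to the simulated original.
    provenance: object = field(default="external", compare=False)

    def __post_init__(self) -> None:
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("duplicate class labels")
        labels = set(self.class_labels)
        seen: set[str] = set()
        for rec in self.records:
            if rec.case_id in seen:
                raise ManifestError(f"duplicate case_id {rec.case_id!r}")
            seen.add(rec.case_id)
            if rec.syndrome not in labels:
                raise ManifestError(
                    f"record {rec.case_id!r}: syndrome {rec.syndrome!r} not among "
                    f"declared class labels"
                )
            if len(rec.embedding) != self.embed_dim:
                raise ManifestError(
                    f"record {rec.case_id!r}: embedding length {len(rec.embedding)} "
                    f"!= embed_dim {self.embed_dim}"
                )

    def __len__(self) -> int:
        return len(self.records)

    # -- array views ---------------------------------------------------------

    def embedding_matrix(self) -> np.ndarray:
        """(n, embed_dim) float array of embeddings, record order."""
        if not self.records:
            return np.empty((0, self.embed_dim), dtype=float)
        return np.array([r.embedding for r in self.records], dtype=float)

    def label_array(self) -> np.ndarray:
        return np.array([r.syndrome for r in self.records], dtype=object)

    def to_Xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.embedding_matrix(), self.label_array()

    # -- subsetting ----------------------------------------------------------

    def by_class(self) -> dict[str, list[PatientRecord]]:
        groups: dict[str, list[PatientRecord]] = {c: [] for c in self.class_labels}
        for rec in self.records:
            groups[rec.syndrome].append(rec)
        return groups

    def filter(self, covariate_filter: Mapping[str, str] | None) -> "CohortManifest":
        """Records passing ``{covariate: value}`` equality filters (None = all)."""
        if not covariate_filter:
            return self
        for name in covariate_filter:
            if name not in ("sex", "ethnicity", "treated"):
                raise KeyError(f"unknown covariate {name!r} in filter")
        kept = tuple(
            r
            for r in self.records
            if all(r.covariate(k) == v for k, v in covariate_filter.items())
        )
        return replace(self, records=kept, provenance="external")

    def subset(self, records: Iterable[PatientRecord]) -> "CohortManifest":
        return replace(self, records=tuple(records), provenance="external")

    def class_sizes(self) -> dict[str, int]:
        return {c: len(g) for c, g in self.by_class().items()}


# ---------------------------------------------------------------------------
# manifest file I/O
# ---------------------------------------------------------------------------


def _format_embedding(values: Sequence[float]) -> str:
    return ";".join(repr(float(v)) for v in values)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest to ``path`` in the package's CSV dialect."""
    rows = []
    for rec in manifest.records:
        rows.append(
            {
                "case_id": rec.case_id,
                "syndrome": rec.syndrome,
                "sex": rec.sex,
                "ethnicity": rec.ethnicity,
                "age": repr(float(rec.age)),
                "treated": rec.treated,
                "annotations": rec.annotations,
                "embedding": _format_embedding(rec.embedding),
            }
        )
    frame = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS), dtype=object)
    buf = io.StringIO()
    buf.write("#class_labels=" + ",".join(manifest.class_labels) + "\n")
    buf.write("#embed_dim=" + str(manifest.embed_dim) + "\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a manifest written by :func:`write_manifest`.

    Malformed rows, inconsistent embedding lengths and duplicate case ids
    raise :class:`ManifestError` naming the offending case.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    class_labels: tuple[str, ...] | None = None
    embed_dim: int | None = None
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if line.startswith("#class_labels="):
            declared = line[len("#class_labels=") :]
            class_labels = tuple(declared.split(",")) if declared else ()
        elif line.startswith("#embed_dim="):
            embed_dim = int(line[len("#embed_dim=") :])
    body = "\n".join(lines[body_start:])
    frame = pd.read_csv(io.StringIO(body), dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")

    records: list[PatientRecord] = []
    for _, row in frame.iterrows():
        case_id = row["case_id"]
        try:
            emb = tuple(float(v) for v in row["embedding"].split(";")) if row[
                "embedding"
            ] else ()
            rec = PatientRecord(
                case_id=case_id,
                syndrome=row["syndrome"],
                sex=row["sex"],
                ethnicity=row["ethnicity"],
                age=float(row["age"]),
                treated=row["treated"],
                annotations=row["annotations"],
                embedding=emb,
            )
        except (ValueError, KeyError) as exc:
            raise ManifestError(f"malformed row for case_id {case_id!r}: {exc}") from exc
        records.append(rec)

    if class_labels is None:
        class_labels = tuple(sorted({r.syndrome for r in records}))
    if embed_dim is None:
        if not records:
            raise ManifestError("empty manifest without an #embed_dim header")
        embed_dim = len(records[0].embedding)
    return CohortManifest(
        records=tuple(records),
        class_labels=class_labels,
        embed_dim=embed_dim,
        provenance="external",
    )
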