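"""Synthetic cohort simulator.

Generates cohort manifests with the statistical structure the downstream
analysis assumes: k syndrome classes with class-specific embedding centroids,
isotropic within-class Gaussian noise, demographic covariates drawn from
per-class proportions, and optional additive covariate shifts (ethnicity-
and/or sex-specific, optionally class-specific) whose magnitude is the
planted "confounder effect".

Geometry
--------
Class centroids are the vertices ``a * e_i`` of a scaled standard simplex
(centred, then rotated by a seeded random orthogonal map), so every pair of
centroids sits at exactly ``class_separation * noise_sd`` apart.  This
requires ``embed_dim >= n_classes``; configurations that cannot place the
requested number of exactly equidistant centroids are rejected.  Explicit
per-class centroids may be supplied instead for structured geometries
(e.g. a mutually confusable triple plus well-separated outgroups).

Confounder shifts are additive vectors of the stated magnitude (in units of
``noise_sd``) along a direction drawn once from ``direction_seed`` — so
replicate populations share the same planted effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seeding import derive_rng
from .cohort import ETHNICITIES, SEXES, CohortManifest, PatientRecord

__all__ = ["ConfounderEffect", "SimulationConfig", "generate_population"]

_COVARIATE_VALUES = {"sex": SEXES, "ethnicity": ETHNICITIES}

DEFAULT_SEX_PROPORTIONS = {"male": 0.5, "female": 0.5}
DEFAULT_ETHNICITY_PROPORTIONS = {"EUR": 0.5, "AFR": 0.5, "other": 0.0}


@dataclass(frozen=True)
class ConfounderEffect:
    """An additive covariate-specific embedding shift planted in one class.

    Parameters
    ----------
    class_label
        Class the shift applies to, or ``"ALL"`` for every class.
    covariate, covariate_value
        Which subgroup is shifted, e.g. ``("ethnicity", "AFR")``.
    magnitude
        Shift length in units of ``noise_sd``; must be >= 0.
    direction_seed
        Seeds the (fixed) random unit direction of the shift.
    """

    class_label: str
    covariate: str
    covariate_value: str
    magnitude: float
    direction_seed: int = 0

    def __post_init__(self) -> None:
        if self.covariate not in _COVARIATE_VALUES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.covariate_value not in _COVARIATE_VALUES[self.covariate]:
            raise ValueError(
                f"unknown {self.covariate} value {self.covariate_value!r}"
            )
        if self.magnitude < 0:
            raise ValueError("shift magnitude must be >= 0")

    def direction(self, dim: int) -> np.ndarray:
        rng = derive_rng(
            self.direction_seed, "confounder-direction", self.class_label,
            self.covariate, self.covariate_value,
        )
        v = rng.standard_normal(dim)
        return v / np.linalg.norm(v)


def _validate_proportions(name: str, props: Mapping[str, float], allowed) -> None:
    for key, p in props.items():
        if key not in allowed:
            raise ValueError(f"unknown {name} category {key!r}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} proportion for {key!r} outside [0, 1]")
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated population; deterministic given seed."""

    class_labels: tuple[str, ...] = ("MPS I", "MPS II", "ML", "SLOS", "NCBRS")
    class_sizes: tuple[int, ...] = (60, 60, 60, 60, 60)
    embed_dim: int = 16
    class_separation: float = 3.0
    noise_sd: float = 1.0
    sex_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"ALL": dict(DEFAULT_SEX_PROPORTIONS)}
    )
    ethnicity_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"ALL": dict(DEFAULT_ETHNICITY_PROPORTIONS)}
    )
    confounder_effects: tuple[ConfounderEffect, ...] = ()
    class_centroids: tuple[tuple[float, ...], ...] | None = None
    age_range: tuple[float, float] = (1.0, 40.0)
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def __post_init__(self) -> None:
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("duplicate class labels")
        if len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes must have one entry per class")
        if any(n < 1 for n in self.class_sizes):
            raise ValueError("every class size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.class_centroids is None and self.embed_dim < self.n_classes:
            raise ValueError(
                f"embed_dim {self.embed_dim} < n_classes {self.n_classes}: cannot "
                "place equidistant centroids (supply class_centroids explicitly "
                "for lower-dimensional geometries)"
            )
        if self.class_centroids is not None:
            if len(self.class_centroids) != self.n_classes:
                raise ValueError("class_centroids must have one centroid per class")
            dims = {len(c) for c in self.class_centroids}
            if dims != {self.embed_dim}:
                raise ValueError("class_centroids dimensions must equal embed_dim")
        if not self.age_range[0] <= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min <= max")
        for name, per_class, allowed in (
            ("sex", self.sex_proportions, SEXES),
            ("ethnicity", self.ethnicity_proportions, ETHNICITIES),
        ):
            for cls, props in per_class.items():
                if cls != "ALL" and cls not in self.class_labels:
                    raise ValueError(f"{name} proportions given for unknown class {cls!r}")
                _validate_proportions(name, props, allowed)

    def proportions_for(self, covariate: str, class_label: str) -> dict[str, float]:
        per_class = (
            self.sex_proportions if covariate == "sex" else self.ethnicity_proportions
        )
        props = per_class.get(class_label, per_class.get("ALL"))
        if props is None:
            raise ValueError(f"no {covariate} proportions for class {class_label!r}")
        return dict(props)


def _random_orthogonal(dim: int, rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix with the R-diagonal sign fix gives a Haar-
    # distributed orthogonal map, deterministically from rng.
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


def place_centroids(config: SimulationConfig) -> np.ndarray:
    """(k, embed_dim) centroid matrix with exact pairwise separation."""
    if config.class_centroids is not None:
        return np.array(config.class_centroids, dtype=float)
    k, d = config.n_classes, config.embed_dim
    sep = config.class_separation * config.noise_sd
    # a*e_i vertices have pairwise distance a*sqrt(2)
    vertices = np.zeros((k, d))
    vertices[:, :k] = np.eye(k) * (sep / np.sqrt(2.0))
    vertices -= vertices.mean(axis=0)
    rotation = _random_orthogonal(d, derive_rng(config.seed, "centroid-rotation"))
    return vertices @ rotation.T


def _draw_categorical(
    rng: np.random.Generator, props: Mapping[str, float], categories: Sequence[str]
) -> str:
    keys = [c for c in categories if c in props]
    p = np.array([props[c] for c in keys], dtype=float)
    return str(keys[rng.choice(len(keys), p=p / p.sum())])


def generate_population(config: SimulationConfig) -> CohortManifest:
    """Simulate a cohort manifest from ``config``; deterministic given seed.

    Each record's embedding is its class centroid, plus any confounder shifts
    matching its covariates, plus isotropic Gaussian noise of sd ``noise_sd``.
    """
    centroids = place_centroids(config)
    shift_vectors = {
        effect: effect.magnitude * config.noise_sd * effect.direction(config.embed_dim)
        for effect in config.confounder_effects
    }

    records: list[PatientRecord] = []
    case_index = 0
    for c, label in enumerate(config.class_labels):
        rng = derive_rng(config.seed, "class-records", label)
        sex_props = config.proportions_for("sex", label)
        eth_props = config.proportions_for("ethnicity", label)
        for _ in range(config.class_sizes[c]):
            case_index += 1
            sex = _draw_categorical(rng, sex_props, SEXES)
            ethnicity = _draw_categorical(rng, eth_props, ETHNICITIES)
            age = float(rng.uniform(*config.age_range))
            treated = str(rng.choice(["yes", "no"]))
            x = centroids[c].copy()
            for effect, vec in shift_vectors.items():
                if effect.class_label not in ("ALL", label):
                    continue
                if effect.covariate == "sex" and sex == effect.covariate_value:
                    x = x + vec
                elif (
                    effect.covariate == "ethnicity"
                    and ethnicity == effect.covariate_value
                ):
                    x = x + vec
            x = x + rng.normal(0.0, config.noise_sd, config.embed_dim)
            records.append(
                PatientRecord(
                    case_id=f"case-{case_index:05d}",
                    syndrome=label,
                    sex=sex,
                    ethnicity=ethnicity,
                    age=age,
                    treated=treated,
                    embedding=tuple(float(v) for v in x),
                )
            )
    return CohortManifest(
        records=tuple(records),
        class_labels=tuple(config.class_labels),
        embed_dim=config.embed_dim,
        provenance=config,
    )
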