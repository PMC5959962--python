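import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenoconfound.cohort import CohortManifest, PatientRecord
from phenoconfound.simulate import SimulationConfig, generate_population

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(case_id, syndrome, embedding, sex="female", ethnicity="EUR",
                age=10.0, treated="no"):
    return PatientRecord(
        case_id=case_id, syndrome=syndrome, sex=sex, ethnicity=ethnicity,
        age=age, treated=treated, embedding=tuple(float(v) for v in embedding),
    )


@pytest.fixture(scope="session")
def small_manifest():
    """Three well-separated classes of 20, 4-d embeddings."""
    cfg = SimulationConfig(
        class_labels=("A", "B", "C"),
        class_sizes=(20, 20, 20),
        embed_dim=4,
        class_separation=6.0,
        seed=42,
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def male_constrained_manifest():
    """Fixture mirroring the real-cohort constraint: the smallest male
    subgroup (class 'MPS I') has exactly 20 records; every other class has
    more.  Embeddings are placeholder 2-d vectors."""
    labels = ("MPS I", "MPS II", "ML", "SLOS", "NCBRS")
    male_counts = {"MPS I": 20, "MPS II": 38, "ML": 25, "SLOS": 24, "NCBRS": 22}
    female_counts = {"MPS I": 15, "MPS II": 2, "ML": 20, "SLOS": 21, "NCBRS": 18}
    rng = np.random.default_rng(7)
    records = []
    i = 0
    for cls in labels:
        for sex, count in (("male", male_counts[cls]), ("female", female_counts[cls])):
            for _ in range(count):
                i += 1
                records.append(
                    make_record(f"case-{i:04d}", cls, rng.normal(size=2), sex=sex)
                )
    return CohortManifest(
        records=tuple(records), class_labels=labels, embed_dim=2
    )
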