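"""Gestalt classifier: fitting, scoring, LOO confusion, AUROC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoconfound.cohort import CohortManifest
from phenoconfound.metrics import accuracy
from phenoconfound.model import (
    GestaltClassifier,
    auroc_from_scores,
    binary_auroc,
    fit_model,
    loo_confusion,
    score_case,
)
from phenoconfound.simulate import SimulationConfig, generate_population

from conftest import make_record


# -- fitting -----------------------------------------------------------------


def test_fit_exact_means_and_degenerate_sd():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    y = np.array(["a", "a", "b", "b"])
    clf = GestaltClassifier().fit(X, y)
    assert np.array_equal(clf.centroids_, [[0, 0], [1, 1]])
    # duplicate records: SD floored, prediction = nearest centroid
    assert clf.pooled_within_sd_ == clf.sd_floor
    assert list(clf.predict([[0.1, 0.1], [0.9, 0.9]])) == ["a", "b"]


def test_fit_invariant_to_record_order():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 5))
    y = np.array(["a", "b", "c"] * 10)
    perm = rng.permutation(30)
    clf1 = GestaltClassifier().fit(X, y)
    clf2 = GestaltClassifier().fit(X[perm], y[perm])
    assert np.allclose(clf1.centroids_, clf2.centroids_)
    assert math.isclose(clf1.pooled_within_sd_, clf2.pooled_within_sd_)


def test_fit_rejects_singleton_class():
    X = np.zeros((3, 2))
    y = np.array(["a", "a", "lonely"])
    with pytest.raises(ValueError, match="lonely"):
        GestaltClassifier().fit(X, y)


def test_centroid_estimates_within_standard_error():
    cfg = SimulationConfig(
        class_labels=("A", "B", "C"), class_sizes=(50,) * 3,
        embed_dim=5, class_separation=4.0, seed=17,
    )
    m = generate_population(cfg)
    clf = fit_model(m)
    from phenoconfound.simulate import place_centroids

    true = place_centroids(cfg)
    order = np.argsort(np.array(cfg.class_labels))
    se = 1.0 / np.sqrt(50)
    assert np.all(np.abs(clf.centroids_ - true[order]) < 3 * se + 1e-9)


# -- scoring -----------------------------------------------------------------


def test_score_closed_form_two_centroids():
    # 1-d, centroids 0 and 2, sd 1, x = 0.5: score ratio = e
    clf = GestaltClassifier().fit(
        np.array([[-1.0], [1.0], [1.5], [2.5]]), np.array(["a", "a", "b", "b"])
    )
    clf.centroids_ = np.array([[0.0], [2.0]])
    clf.pooled_within_sd_ = 1.0
    p = clf.predict_proba([[0.5]])[0]
    e = math.exp(1.0)
    assert np.allclose(p, [e / (1 + e), 1 / (1 + e)], atol=1e-12)


def test_score_at_centroid_with_distant_alternatives():
    rec = make_record("r", "A", (0.0, 0.0))
    model = GestaltClassifier().fit(
        np.array([[0.0, 0.0], [0.0, 0.0], [20.0, 0.0], [20.0, 0.0]]),
        np.array(["A", "A", "B", "B"]),
    )
    model.pooled_within_sd_ = 1.0  # nearest other centroid 20 sd away
    sv = score_case(rec, model)
    assert sv.scores[0] > 1 - 1e-6 and sv.predicted == "A"


def test_equidistant_scores_uniform_and_tie_lexicographic():
    X = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
    y = np.array(["b", "b", "a", "a"])
    model = GestaltClassifier().fit(X, y)
    rec = make_record("r", "a", (0.0, 5.0))  # equidistant from both centroids
    sv = score_case(rec, model)
    assert np.allclose(sv.scores, [0.5, 0.5])
    assert sv.predicted == "a"  # lexicographically smallest among ties


def test_dimension_mismatch_raises():
    model = GestaltClassifier().fit(np.zeros((4, 3)), np.array(["a", "a", "b", "b"]))
    with pytest.raises(ValueError, match="dimension"):
        model.predict_proba([[1.0, 2.0]])


def test_scores_sum_to_one_far_from_all_centroids():
    # softmax normalisation must survive extreme distances
    model = GestaltClassifier().fit(
        np.array([[0.0], [0.1], [5.0], [5.1]]), np.array(["a", "a", "b", "b"])
    )
    p = model.predict_proba([[1e4]])[0]
    assert math.isclose(p.sum(), 1.0, abs_tol=1e-9)


# -- LOO confusion -----------------------------------------------------------


def test_loo_counts_conserved(small_manifest):
    cm = loo_confusion(small_manifest)
    assert cm.total == len(small_manifest)
    sizes = small_manifest.class_sizes()
    assert {c: int(s) for c, s in zip(cm.labels, cm.row_sums)} == sizes


def test_loo_excludes_own_record_from_centroid():
    # an extreme outlier dragged into its own centroid would be self-
    # confirmed; with LOO its centroid excludes it, so it is misassigned
    records = [
        make_record("a1", "A", (0.0, 0.0)),
        make_record("a2", "A", (0.2, 0.0)),
        make_record("a3", "A", (10.0, 0.0)),  # outlier, nearer to B
        make_record("b1", "B", (12.0, 0.0)),
        make_record("b2", "B", (12.2, 0.0)),
    ]
    m = CohortManifest(tuple(records), ("A", "B"), 2)
    cm = loo_confusion(m)
    a, b = cm.index_of("A"), cm.index_of("B")
    assert cm.counts[a, b] == 1  # the outlier


def test_strong_separation_tprs(small_manifest):
    cm = loo_confusion(small_manifest)
    assert np.all(np.diag(cm.probabilities) >= 0.95)


def test_loo_accuracy_monotone_in_separation():
    # 3-point separation grid, 20 seeds: mean accuracy never decreases by
    # more than sampling noise
    grid = (1.0, 2.0, 3.0)
    means = []
    for sep in grid:
        accs = []
        for seed in range(20):
            cfg = SimulationConfig(
                class_sizes=(30,) * 5, embed_dim=6,
                class_separation=sep, seed=1000 + seed,
            )
            accs.append(accuracy(loo_confusion(generate_population(cfg))))
        means.append(np.mean(accs))
    assert means[0] < means[1] < means[2] + 0.02
    assert means[1] <= means[2] + 0.02


# -- AUROC -------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([0.9, 0.8], [0.1, 0.2], 1.0),  # perfect separation
        ([0.5, 0.5], [0.5, 0.5], 0.5),  # all ties
        ([0.9, 0.4], [0.6, 0.1], 0.75),  # 3 of 4 concordant pairs
    ],
)
def test_auroc_reference_values(a, b, expected):
    assert auroc_from_scores(a, b) == pytest.approx(expected, abs=1e-12)


@given(
    st.lists(st.integers(0, 10), min_size=1, max_size=50),
    st.lists(st.integers(0, 10), min_size=1, max_size=50),
)
@settings(max_examples=200)
def test_auroc_matches_pair_counting_oracle(a, b):
    pairs = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    oracle = pairs / (len(a) * len(b))
    assert abs(auroc_from_scores(a, b) - oracle) < 1e-12
    assert abs(auroc_from_scores(a, b) + auroc_from_scores(b, a) - 1.0) < 1e-12


def test_binary_auroc_separated_cohorts():
    a = [make_record(f"a{i}", "A", (0.0 + 0.1 * i, 0.0)) for i in range(5)]
    b = [make_record(f"b{i}", "B", (8.0 + 0.1 * i, 0.0)) for i in range(5)]
    assert binary_auroc(a, b) == 1.0
    assert binary_auroc(b, a) == 0.0


def test_binary_auroc_rejects_small_cohorts():
    a = [make_record("a0", "A", (0.0,))]
    b = [make_record(f"b{i}", "B", (1.0,)) for i in range(3)]
    with pytest.raises(ValueError):
        binary_auroc(a, b)
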