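"""Confusion-matrix algebra: TPR, accuracy, binarization, MCC, baselines."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from phenoconfound.metrics import (
    BinaryContingency,
    ConfusionMatrix,
    accuracy,
    binarize,
    expected_random_accuracy,
    mcc,
    tpr,
)

EXAMPLE = ConfusionMatrix(
    labels=("A", "B", "C"),
    counts=np.array([[5, 1, 0], [2, 6, 1], [0, 0, 7]]),
)


def phi_coefficient(tp, fp, fn, tn):
    """Independent oracle: MCC as the Pearson correlation of the 0/1
    true and predicted label vectors."""
    y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    if len(y_true) < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y_true, y_pred)[0, 1]
    return 0.0 if np.isnan(r) else float(r)


# -- TPR / accuracy ----------------------------------------------------------


def test_tpr_and_accuracy_worked_example():
    assert tpr(EXAMPLE, "A") == pytest.approx(5 / 6)
    assert tpr(EXAMPLE, "B") == pytest.approx(2 / 3)
    assert tpr(EXAMPLE, "C") == 1.0
    assert accuracy(EXAMPLE) == pytest.approx(18 / 22)


def test_perfect_and_uniform_matrices():
    perfect = ConfusionMatrix(("A", "B", "C"), np.diag([5, 5, 5]))
    assert accuracy(perfect) == 1.0 and all(
        tpr(perfect, c) == 1.0 for c in perfect.labels
    )
    uniform = ConfusionMatrix(("A", "B", "C"), np.ones((3, 3), dtype=int))
    assert accuracy(uniform) == pytest.approx(1 / 3)
    assert tpr(uniform, "B") == pytest.approx(1 / 3)


def test_empty_row_tpr_is_missing_not_zero():
    cm = ConfusionMatrix(("A", "B"), np.array([[0, 0], [1, 3]]))
    assert math.isnan(tpr(cm, "A"))
    assert cm.empty_rows == ("A",)


# -- binarization ------------------------------------------------------------


def test_binarize_worked_example():
    bc = binarize(EXAMPLE, "A")
    assert (bc.tp, bc.fn, bc.fp, bc.tn) == (5, 1, 2, 14)
    assert bc.total == 22


def test_binarize_identity_and_degenerate():
    bc = binarize(ConfusionMatrix(("A", "B"), np.diag([3, 3])), "A")
    assert (bc.tp, bc.fn, bc.fp, bc.tn) == (3, 0, 0, 3)
    bc1 = binarize(ConfusionMatrix(("A",), np.array([[4]])), "A")
    assert (bc1.tp, bc1.fn, bc1.fp, bc1.tn) == (4, 0, 0, 0)


@given(
    st.integers(2, 6).flatmap(
        lambda k: st.lists(
            st.lists(st.integers(0, 20), min_size=k, max_size=k),
            min_size=k, max_size=k,
        )
    )
)
def test_binarize_partitions_total(rows):
    counts = np.array(rows)
    if counts.sum() == 0:
        counts[0, 0] = 1
    labels = tuple(f"c{i}" for i in range(counts.shape[0]))
    cm = ConfusionMatrix(labels, counts)
    for c in labels:
        assert binarize(cm, c).total == cm.total
    # accuracy is the prior-weighted mean of TPRs
    priors = cm.row_sums / cm.total
    tprs = np.array([tpr(cm, c) for c in labels])
    mask = cm.row_sums > 0
    assert accuracy(cm) == pytest.approx(
        float(np.sum(priors[mask] * tprs[mask])), abs=1e-12
    )


# -- MCC ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "table, expected",
    [
        ((10, 0, 0, 10), 1.0),
        ((0, 10, 10, 0), -1.0),
        ((6, 1, 2, 5), 28 / math.sqrt(2352)),
        ((0, 0, 5, 5), 0.0),  # zero-margin convention
    ],
)
def test_mcc_reference_values(table, expected):
    tp, fp, fn, tn = table
    assert mcc(BinaryContingency(tp=tp, fp=fp, fn=fn, tn=tn)) == pytest.approx(
        expected, abs=1e-12
    )


def test_mcc_exhaustive_small_tables():
    """Every contingency table with total <= 12 against two independent
    oracles: the phi coefficient and scikit-learn."""
    for tp, fp, fn in itertools.product(range(13), repeat=3):
        for tn in range(13 - tp - fp - fn):
            total = tp + fp + fn + tn
            if total == 0:
                continue
            ours = mcc(BinaryContingency(tp=tp, fp=fp, fn=fn, tn=tn))
            assert abs(ours - phi_coefficient(tp, fp, fn, tn)) < 1e-12
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            if len(set(y_true)) > 1 or len(set(y_pred)) > 1:
                assert abs(ours - matthews_corrcoef(y_true, y_pred)) < 1e-12


@given(st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0))
def test_mcc_symmetries(table):
    tp, fp, fn, tn = table
    base = mcc(BinaryContingency(tp=tp, fp=fp, fn=fn, tn=tn))
    # simultaneous swap tp<->tn, fp<->fn leaves MCC unchanged
    assert mcc(BinaryContingency(tp=tn, fp=fn, fn=fp, tn=tp)) == pytest.approx(base)
    # flipping the predicted labels negates MCC (unless a margin is zero)
    flipped = mcc(BinaryContingency(tp=fp, fp=tp, fn=tn, tn=fn))
    if base != 0.0:
        assert flipped == pytest.approx(-base, abs=1e-12)


# -- random-expectation baseline ---------------------------------------------


def test_expected_random_accuracy():
    assert expected_random_accuracy([10] * 5) == pytest.approx(0.2)
    assert expected_random_accuracy([10, 30]) == pytest.approx(0.625)
    assert expected_random_accuracy([7]) == 1.0
    with pytest.raises(ValueError):
        expected_random_accuracy([])


# -- serialisation -----------------------------------------------------------


def test_confusion_tsv_roundtrip(tmp_path):
    path = tmp_path / "cm.tsv"
    EXAMPLE.to_tsv(path)
    assert ConfusionMatrix.from_tsv(path) == EXAMPLE
    probs_path = tmp_path / "cm.probs.tsv"
    EXAMPLE.to_tsv(probs_path, probabilities=True)
    assert "0.8333" in probs_path.read_text()[:200]
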