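"""Down-sampling protocol, repeated experiments, ΔMCC/2·SD rule, size sweep."""

import numpy as np
import pytest

from phenoconfound.cohort import CohortManifest
from phenoconfound.confounder import (
    ExperimentResult,
    ExperimentSpec,
    assess_confounder,
    fit_tpr_trend,
    greatest_common_size,
    run_repeated_experiment,
    size_sweep,
)
from phenoconfound.simulate import SimulationConfig, generate_population

from conftest import make_record


# -- greatest common size ----------------------------------------------------


def test_greatest_common_size_male_protocol(male_constrained_manifest):
    # the binding constraint is the smallest male subgroup: 20
    assert greatest_common_size(male_constrained_manifest, {"sex": "male"}) == 20
    assert greatest_common_size(male_constrained_manifest, None) == 35


def test_greatest_common_size_small_filter():
    records = [make_record(f"a{i}", "A", (0.0, 0.0), ethnicity="AFR") for i in range(3)]
    records += [make_record(f"a{i+3}", "A", (0.0, 0.0)) for i in range(4)]
    records += [make_record(f"b{i}", "B", (1.0, 1.0), ethnicity="AFR") for i in range(6)]
    m = CohortManifest(tuple(records), ("A", "B"), 2)
    assert greatest_common_size(m, {"ethnicity": "AFR"}) == 3


def test_greatest_common_size_empty_class_errors(male_constrained_manifest):
    with pytest.raises(ValueError, match="MPS I"):
        # every record is untreated, so the filter empties every class;
        # the error names the first class with no passing records
        greatest_common_size(male_constrained_manifest, {"treated": "yes"})


def test_experiment_refuses_oversized_sample(male_constrained_manifest):
    spec = ExperimentSpec(sample_size=21, cohort_filters={"sex": "male"},
                          n_iterations=2, master_seed=0)
    with pytest.raises(ValueError, match="greatest common size"):
        run_repeated_experiment(male_constrained_manifest, spec)


# -- repeated experiments ----------------------------------------------------


@pytest.fixture(scope="module")
def signal_manifest():
    cfg = SimulationConfig(
        class_labels=("A", "B", "C"), class_sizes=(25,) * 3,
        embed_dim=4, class_separation=3.0, seed=2,
    )
    return generate_population(cfg)


def test_full_cohort_sampling_has_zero_sd(signal_manifest):
    spec = ExperimentSpec(sample_size=25, n_iterations=3, master_seed=0)
    result = run_repeated_experiment(signal_manifest, spec)
    assert np.allclose(result.sd_tpr, 0, atol=1e-12)
    assert np.allclose(result.sd_mcc, 0, atol=1e-12)
    assert result.confusions[0] == result.confusions[1] == result.confusions[2]


def test_experiment_deterministic(signal_manifest):
    spec = ExperimentSpec(sample_size=15, n_iterations=4, master_seed=99)
    r1 = run_repeated_experiment(signal_manifest, spec)
    r2 = run_repeated_experiment(signal_manifest, spec)
    assert np.array_equal(r1.tpr_values, r2.tpr_values)
    assert np.array_equal(r1.mcc_values, r2.mcc_values)


def test_iteration_seeds_independent_of_iteration_count(signal_manifest):
    """Iteration i depends only on (master_seed, filter, size, i): truncating
    the experiment reproduces its prefix."""
    long = run_repeated_experiment(
        signal_manifest, ExperimentSpec(15, None, 5, master_seed=7)
    )
    short = run_repeated_experiment(
        signal_manifest, ExperimentSpec(15, None, 3, master_seed=7)
    )
    for i in range(3):
        assert long.confusions[i] == short.confusions[i]


def test_experiment_statistics_shapes(signal_manifest):
    spec = ExperimentSpec(sample_size=10, n_iterations=5, master_seed=1)
    r = run_repeated_experiment(signal_manifest, spec)
    assert r.tpr_values.shape == (3, 5)
    assert np.all((0 <= r.tpr_values) & (r.tpr_values <= 1))
    assert np.all((-1 <= r.mcc_values) & (r.mcc_values <= 1))
    assert len(r.confusions) == 5
    assert all(cm.total == 30 for cm in r.confusions)


# -- the ΔMCC / 2·SD rule ----------------------------------------------------


def result_with_mccs(per_class_mccs, labels=("A",), sample_size=19):
    """Construct an ExperimentResult carrying prescribed per-iteration MCCs."""
    arr = np.array(per_class_mccs, dtype=float)
    k, n = arr.shape
    return ExperimentResult(
        labels=tuple(labels),
        sample_size=sample_size,
        n_iterations=n,
        tpr_values=np.zeros_like(arr),
        mcc_values=arr,
        accuracy_values=np.zeros(n),
        confusions=(),
    )


def test_rule_worked_example():
    control = result_with_mccs([[0.48, 0.49, 0.50, 0.51, 0.52]])
    confounder = result_with_mccs([[0.56] * 5])
    a = assess_confounder(confounder, control).for_class("A")
    assert a.delta_mcc == pytest.approx(0.06)
    assert a.sd_control == pytest.approx(np.std([0.48, 0.49, 0.50, 0.51, 0.52], ddof=1))
    assert a.ratio == pytest.approx(3.7947, abs=1e-3)
    assert a.flagged is True


def test_rule_null_and_boundary():
    control = result_with_mccs([[0.4, 0.5, 0.6]])
    same = assess_confounder(control, control).for_class("A")
    assert same.ratio == 0.0 and same.flagged is False
    # confounder lower by exactly 2 SD: strict inequality -> not flagged
    sd = float(np.std([0.4, 0.5, 0.6], ddof=1))
    confounder = result_with_mccs([[0.5 - 2 * sd] * 3])
    at_boundary = assess_confounder(confounder, control).for_class("A")
    assert at_boundary.ratio == pytest.approx(-2.0)
    assert at_boundary.flagged is False


def test_rule_zero_sd_indeterminate():
    control = result_with_mccs([[0.5, 0.5, 0.5]])
    confounder = result_with_mccs([[0.7, 0.7, 0.7]])
    a = assess_confounder(confounder, control).for_class("A")
    assert a.ratio is None and a.flagged is None


def test_rule_requires_matching_design():
    a = result_with_mccs([[0.1, 0.2]], sample_size=10)
    b = result_with_mccs([[0.1, 0.2]], sample_size=20)
    with pytest.raises(ValueError, match="sample size"):
        assess_confounder(a, b)


# -- size sweep --------------------------------------------------------------


def test_trend_fit_exact_linear():
    fit = fit_tpr_trend([10, 20, 30, 40], [0.2, 0.4, 0.6, 0.8])
    assert fit.slope == pytest.approx(0.02)
    assert fit.r == pytest.approx(1.0)


def test_trend_fit_flat():
    fit = fit_tpr_trend([10, 20, 30, 40], [0.7, 0.7, 0.7, 0.7])
    assert fit.slope == pytest.approx(0.0, abs=1e-12)


def test_trend_fit_refuses_underdetermined():
    with pytest.raises(ValueError, match="3 points"):
        fit_tpr_trend([10, 20], [0.1, 0.2])


def test_size_sweep_structure(signal_manifest):
    result = size_sweep(
        signal_manifest, sizes=(10, 15, 20), n_iterations=3, master_seed=5
    )
    assert result.tpr_values.shape == (3, 3, 3)
    for c in result.labels:
        assert np.isfinite(result.fits[c].slope)
        assert 0 <= result.fits[c].p_value <= 1


def test_size_sweep_validates_sizes(signal_manifest):
    with pytest.raises(ValueError, match="increasing"):
        size_sweep(signal_manifest, sizes=(20, 10))
    with pytest.raises(ValueError, match="greatest common size"):
        size_sweep(signal_manifest, sizes=(10, 30))
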