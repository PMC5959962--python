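# phenoconfound

Quantify how distinguishable syndrome phenotypes are from classifier
similarity ("gestalt") scores — and test whether cohort size, ethnicity or
sex confounds that distinguishability.

Computer-vision tools for syndromology compare a patient's facial photograph
to learned syndrome models and return per-syndrome similarity scores.  When
the accuracy of such a classifier is read as a measure of how separable two
disease phenotypes are, it matters that the measurement is not driven by the
composition of the cohorts instead of the phenotypes: a cohort that is
larger, or skewed in sex or ancestry, can look "more distinguishable" for
reasons that have nothing to do with the disease.  This package implements a
systematic confounder-analysis framework for that setting, aimed at
researchers evaluating phenotype classifiers on small clinical cohorts
(e.g. inborn errors of metabolism such as the mucopolysaccharidoses, where
facial gestalts overlap strongly).

Because real patient photographs and the commercial networks that score them
are not redistributable, the package ships a synthetic cohort simulator
(class-separated Gaussian embeddings with plantable covariate shifts) and a
stand-in gestalt classifier (nearest-centroid with a Gaussian kernel, exposed
as a scikit-learn estimator).  Every analysis runs unchanged on real score
data supplied as a cohort manifest.

## The statistics at the core

For cohorts of embedding vectors, the stand-in classifier fits one centroid
μ_c per syndrome and scores a case x with

    score_c(x) ∝ exp(−‖x − μ_c‖² / 2σ²),   σ = pooled within-class SD,

evaluated leave-one-out (each record is removed from its own class centroid
before being scored).  Cross-tabulating true vs predicted classes gives a
confusion matrix with per-class true positive rates TPR_c on the diagonal of
its row-normalised view.

**Down-sampled repeated experiments.** To remove cohort size as a covariate,
all classes are sampled down to the *greatest common size* available after a
covariate filter (e.g. males only), the evaluation is repeated over
iterations (default 5) with fresh random subsamples, and per-class TPRs and
one-vs-rest Matthews correlation coefficients

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

are aggregated as means and sample SDs.

**The ΔMCC / 2·SD rule.** A covariate-restricted ("homogeneous") experiment
is compared against an unrestricted ("mixed") control at the same sample
size.  Per class,

    ratio = (mean MCC_homogeneous − mean MCC_mixed) / SD(MCC_mixed iterations)

and the covariate is flagged as affecting that class only when |ratio| > 2.

**Cohort-size sweep.** TPR is measured at evenly sized subsets (default
10–40 per class) and every per-iteration TPR is fitted against size by
ordinary least squares (`scipy.stats.linregress`), giving a slope, r and a
two-sided p-value for slope = 0.

**Dendrogram and differential diagnoses.** Classes a classifier mutually
confuses are phenotypically similar: d(i,j) = 1 − (P[i][j]+P[j][i])/2 turns
the confusion probabilities into a distance matrix, clustered by UPGMA into
an ultrametric dendrogram (Newick export).  Separately, each case can be
ranked against a ~300-model library; a wrong diagnosis appearing in more
than 10% of a cohort's top-30 lists is flagged as phenotypically similar.

## Worked example

```python
from phenoconfound import (
    SimulationConfig, ConfounderEffect, generate_population,
    ExperimentSpec, run_repeated_experiment, assess_confounder,
    greatest_common_size, loo_confusion, accuracy, expected_random_accuracy,
    confusion_to_distance, upgma, to_newick,
)

# five syndrome cohorts of 80; an ethnicity-specific facial shift of twice
# the noise SD is planted in the AFR subgroup of MPS I
effect = ConfounderEffect("MPS I", "ethnicity", "AFR", magnitude=2.0, direction_seed=0)
config = SimulationConfig(
    class_labels=("MPS I", "MPS II", "ML", "SLOS", "NCBRS"),
    class_sizes=(80,) * 5,
    embed_dim=6,
    class_separation=1.0,
    confounder_effects=(effect,),
    seed=42,
)
cohort = generate_population(config)

cm = loo_confusion(cohort)
print(f"full-cohort LOO accuracy: {accuracy(cm):.3f} "
      f"(chance: {expected_random_accuracy([80]*5):.2f})")

print("greatest common size, AFR-only:",
      greatest_common_size(cohort, {"ethnicity": "AFR"}))

afr = run_repeated_experiment(
    cohort, ExperimentSpec(sample_size=30, cohort_filters={"ethnicity": "AFR"},
                           n_iterations=5, master_seed=0))
mixed = run_repeated_experiment(
    cohort, ExperimentSpec(sample_size=30, cohort_filters=None,
                           n_iterations=5, master_seed=1))
for a in assess_confounder(afr, mixed):
    print(f"{a.label:7s} dMCC={a.delta_mcc:+.3f} sd_control={a.sd_control:.3f} "
          f"ratio={a.ratio:+.2f} flagged={a.flagged}")

print(to_newick(upgma(confusion_to_distance(cm))))
```

prints

```
full-cohort LOO accuracy: 0.410 (chance: 0.20)
greatest common size, AFR-only: 31
MPS I   dMCC=+0.234 sd_control=0.027 ratio=+8.52 flagged=True
MPS II  dMCC=+0.011 sd_control=0.072 ratio=+0.16 flagged=False
ML      dMCC=+0.069 sd_control=0.081 ratio=+0.85 flagged=False
SLOS    dMCC=+0.061 sd_control=0.084 ratio=+0.72 flagged=False
NCBRS   dMCC=+0.048 sd_control=0.078 ratio=+0.61 flagged=False
(((ML:0.403125,'MPS I':0.403125):0.0234375,NCBRS:0.426562):0.00677083,('MPS II':0.40625,SLOS:0.40625):0.0270833);
```

The classifier separates the five cohorts well above chance (0.41 vs 0.20).
The planted ethnicity effect is detected exactly where it was planted: only
MPS I shows a ΔMCC beyond two control SDs (ratio 8.5) — classifying MPS I in
an ethnically homogeneous cohort works markedly better than in the mixed
setup, the signature of a confounded phenotype model.  The Newick string is
the confusion-derived dendrogram; single comparisons are noisy, so the
`phenoconfound.studies` module aggregates replicate populations (the planted
effect is recovered in ~90% of replicates, with a false-flag rate under 15%
per class when nothing is planted).

A command-line interface mirrors the library: `phenoconfound simulate`,
`experiment`, `confound`, `sweep`, `cluster`, `ddx` and `run` (full pipeline
from one YAML config; see `phenoconfound run --help`).

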