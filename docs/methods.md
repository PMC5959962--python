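# Methods

This note documents the models implemented in `phenoconfound`, the
assumptions behind the synthetic data, the frozen study conditions used by
the test suite and by `scripts/acceptance.py`, and the design decisions made
where the procedure was genuinely open.  It states no empirical result that
the tests or the acceptance script do not themselves compute.

## The measurement problem

Given per-case similarity scores against a set of syndrome models, the
accuracy of the induced classifier is read as a measure of phenotype
distinguishability.  The framework asks whether that measurement is
confounded by cohort composition — size, ethnicity, sex — using three
instruments: down-sampled repeated experiments, the ΔMCC / 2·SD decision
rule, and a cohort-size sweep.  A confusion-probability dendrogram and a
top-K differential-diagnosis analysis summarise which phenotypes the
classifier finds similar.

## Synthetic cohorts

`generate_population` draws, for each of k syndrome classes, records with

* an embedding `x = μ_c + Σ shifts + ε`, with `ε ~ N(0, noise_sd²·I)`;
* covariates sex/ethnicity from per-class proportions, age uniform on
  `age_range`, treatment status uniform on {yes, no};
* class centroids `μ_c` at the vertices of a scaled standard simplex
  (centred, rotated by a seeded Haar-random orthogonal map), so every pair
  of centroids is exactly `class_separation × noise_sd` apart.  This
  construction needs `embed_dim ≥ n_classes`; configurations that cannot
  place exactly equidistant centroids are rejected.  Structured geometries
  (e.g. a confusable triple plus distant outgroups) are supplied as explicit
  `class_centroids`.

A planted confounder effect is an additive vector of `magnitude × noise_sd`
along a unit direction drawn once from `direction_seed` and applied to the
records of one class (or all classes) matching one covariate value.  The
direction is fixed per (class, covariate, value): replicate populations
share the same planted effect, and differ only in sampling.

What the simulator does *not* model: anything image-like (no faces, no
craniofacial geometry), heavy-tailed or correlated score noise, age- or
treatment-dependent phenotype progression, and any particular property of
commercial scoring networks — the Gaussian-embedding assumption is a
stand-in, not a claim about real systems.  Passing tests therefore
demonstrate that the *framework* behaves correctly on data satisfying its
own assumptions, not that any real classifier is (un)confounded.

## The stand-in gestalt classifier

`GestaltClassifier` (a scikit-learn estimator) fits one centroid per class
and a single pooled within-class SD `σ = sqrt(mean ‖residual‖² / dim)`;
scores are the softmax of `−‖x−μ_c‖²/(2σ²)`.  Decisions that needed fixing:

* **Evaluation protocol** — leave-one-out, with the held-out record removed
  only from its *own* class centroid (closed-form downdate); the pooled σ is
  kept from the full fit.  LOO is deterministic and wastes no records, which
  matters at cohort sizes of 10–40.
* **Degenerate fits** — a pooled SD of zero (all-duplicate training data) is
  floored at 1e-9, where prediction reduces to nearest centroid.
* **Ties** — argmax ties resolve to the lexicographically smallest label;
  scores are computed in log space, so cases far from every centroid still
  yield normalised score vectors.
* **Pluggability** — everything downstream consumes confusion matrices or
  score vectors, so real *gestalt* scores can replace the stand-in.

`binary_auroc` scores a two-cohort comparison with the LOO score difference
and computes AUROC as the Mann–Whitney concordance probability (ties count
1/2).  The discriminant is oriented by a canonical cohort key rather than by
argument order, making `auroc(a,b) + auroc(b,a) = 1` an exact identity.

## Metrics

The confusion matrix stores integer counts (source of truth) beside the
row-normalised probability view.  The TPR of a class with no evaluated
cases is *missing* (NaN), never zero: in the down-sampling protocols every
row is populated, so a missing TPR signals a protocol bug rather than a
performance of zero.  The one-vs-rest reduction partitions the matrix total
exactly; MCC of a table with a zero margin is defined as 0 (the dominant
convention; it keeps ΔMCC defined).  The chance-level baseline is
`Σ p_i²` for empirical class priors `p_i` — the accuracy of a predictor
drawing labels from the prior.

## Confounder framework

* Down-sampling samples without replacement within an iteration and redraws
  independently across iterations (overlap allowed); iteration i's
  subsample is a pure function of (master seed, filter, sample size, i), so
  any iteration can be reproduced alone and truncating an experiment
  reproduces its prefix.
* SDs are sample SDs (ddof 1) over the iteration values.
* The flag uses strict inequality |ΔMCC/SD| > 2: a difference *within* two
  control SDs counts as no effect.  A zero control SD leaves the ratio
  undefined and the flag indeterminate rather than false.
* The control ("mixed") experiment is the same sample size with no
  covariate filter, sampled uniformly from the unfiltered pool.
* The size sweep regresses every per-iteration TPR (not iteration means)
  against size — more degrees of freedom for the slope test; sizes default
  to {10, 20, 30, 40}.
* No multiple-testing correction is applied across classes; the per-class
  flags are descriptive, mirroring how the rule is used in practice.

## Similarity clustering

The distance `d(i,j) = 1 − (P[i][j]+P[j][i])/2` is the minimal monotone
transform mapping high mutual confusion to small distance; it is a module
boundary and can be swapped.  Clustering is UPGMA (average linkage),
implemented directly (O(k³), deterministic tie-break: the pair whose
label-sorted names come first) so that scipy's implementation remains an
independent cross-check in the tests.  Node heights use the half-distance
(ultrametric) convention — a merge at cluster distance d sits at height
d/2 — and the Newick export writes branch lengths accordingly, quoting
labels that contain spaces.

## Differential-diagnosis ranking

The library holds the fitted study-class models plus `n_background`
(default 295) background centroids at radius `background_separation × σ`
(default 8) from the centre of the study centroids in seeded random
directions, emulating a ~300-model clinical library.  Rankings are full and
deterministic (ties lexicographic).  The similarity flag is strict
(frequency > 0.10 in the top 30).  Phenotypic-series merging (e.g. both
mucopolysaccharidosis subtypes → "MPS") is a label map applied before
counting; a merged label occupies the best rank of its members.  Whether a
clinical top-30 list is score-thresholded or fixed-length is not knowable
from outside; a fixed-length top-K is implemented.

## Frozen study conditions

`phenoconfound.studies` fixes the synthetic evaluation studies used by the
acceptance tests and `scripts/acceptance.py`.  The conditions were designed
once, with an explicit pilot phase, and are not tuning knobs:

* **Confounder studies** — five classes of 80 (ethnicity 50/50 EUR/AFR),
  embeddings in 6 dimensions, class separation 1.0·σ, planted shift
  2.0·σ on one class's AFR subgroup in a fixed direction; the
  shifted-ethnicity homogeneous cohort (AFR-only) is compared to the mixed
  control at sample size 30 over 5 iterations.  Rationale: a planted shift
  can only confound a centroid classifier if it projects onto the
  inter-class axes — in high dimension a random direction is nearly
  orthogonal to all of them, so a low-dimensional embedding (dim close to
  the class count) is the faithful analogue of covariate variation that
  overlaps the syndrome-relevant feature axes; the shifted-subgroup
  homogeneous comparison is the sensitive one (the shift both removes the
  within-class bimodality and adds distance to the other classes); and a
  class signal comparable to the planted effect represents the scenario the
  rule exists to detect (covariate variation rivalling the phenotype
  signal).  A replicate is a *feasible* population: seeds whose binomial
  ethnicity draw leaves a filtered pool below the sample size advance
  deterministically to the next offset.
* **Null calibration** — separation 0, five cohorts of 40, LOO accuracy
  compared to the 0.20 chance level over 20 population seeds.
* **Size sweep** — separation 1.5·σ ("moderate signal"), 16 dimensions,
  cohorts of 60, sizes 10/20/30/40 with 5 iterations; the per-seed
  statistic is the per-class OLS slope averaged over classes.  Saturating
  signal (separation 10·σ) uses the same design.  Improvement with cohort
  size is driven by centroid-estimation error (∝ σ√(dim/n)) shrinking
  relative to the class separation.
* **Clade recovery** — three classes on an equilateral triangle of side
  1.0·σ plus two classes 8·σ away (explicit centroids, 6 dimensions,
  cohorts of 40); recovery means the confusable triple forms a clade of the
  UPGMA tree.
* **DDx study** — separation 3.0·σ, 16 dimensions, cohorts of 40, a
  300-model library (295 background at 8·σ).

Problem sizes throughout (20 seeds, 50 power replicates, 200 null
replicates) were chosen as the package's own study design: large enough for
the rates being estimated, small enough that the whole acceptance run
completes in well under a minute.

## Numerical notes and known limitations

* All randomness flows through `numpy.random.SeedSequence` derivations of
  one master seed; identical configurations give byte-identical manifests,
  TSVs and summary JSON.
* Iteration SDs over 5 values are noisy (4 degrees of freedom), which makes
  the 2·SD rule anti-conservative; the null study measures the empirical
  per-class flag rate rather than assuming a nominal level.  Overlap
  between iterations drawn from small pools further shrinks the SD
  estimate.
* MCC uses exact integer products before a single square root; tables up to
  ~10⁴ cases are exact to double precision.
* The manifest dialect is deliberately single: UTF-8 CSV, header row,
  `#class_labels=` / `#embed_dim=` comment headers, embeddings as
  semicolon-joined `repr` floats (lossless round-trip).
* The age/treatment-duration covariate is carried in the manifest but no
  analysis is implemented for it (longitudinal structure is out of the
  simulator's scope).
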