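# Methods

`connectocast` re-implements, as a tested pipeline, an analysis that predicts
long-term cancer-related cognitive impairment from *pre-treatment*
resting-state connectome features: graph metrics are extracted from
region-by-region functional-connectivity matrices, impairment is defined
longitudinally against a healthy-control reference, and a nested
recursive-feature-elimination random forest predicts the 1-year outcome.
Because no raw fMRI or cognition data are deposited with the original study,
the package ships a synthetic-cohort generator that reproduces the
*statistical structure* the analysis assumes, so every stage is exercised
end to end with no downloads.

## Connectome metrics

**Binarization.** Each subject's weighted matrix (90 regions by default,
symmetric, zero diagonal) is thresholded at its *minimum connection
density*: edges are admitted in descending absolute weight until no region
is disconnected. Semantics are threshold-based — if admission stops inside
a group of equal-weight edges, the whole tie group is admitted, which makes
binarization idempotent on already-binary matrices; for continuous weights
ties have measure zero and the rule reduces to a pure edge count.
Tie order within a weight class is (lower row, lower column), so results
are fully deterministic. Two modes are provided because the study does not
state which it used: `per_subject` (each subject at its own minimum) and
`cohort_common` (the maximum of all subjects' minima applied to everyone,
the default, so all subjects share one density). Negative weights are
ranked by absolute value.

**Nodal metrics.** On the binary network: degree `k_i`; clustering
coefficient `C_i = 2 t_i / (k_i (k_i − 1))` with `t_i` the edges among
region *i*'s neighbors (0 when `k_i < 2`); betweenness `B_i` as the
*unnormalized* shortest-path load over unordered pairs (the reported
magnitudes, in the hundreds for ~90-region networks, are inconsistent with
[0,1] normalization); participation `P_i = 1 − Σ_s (k_is/k_i)²` over the
modules of a partition. Module detection is greedy modularity maximization
(Clauset–Newman–Moore, via networkx); it is deterministic, and the `seed`
argument exists only so callers can thread one seed uniformly. `Q` is
reported for the returned partition.

**Hubs.** Hub status follows the "mean + 1 SD" convention: a region is a
hub when degree, betweenness or clustering exceeds that metric's mean over
regions by more than one sample SD. Because published hub tables show
fractional degrees, metrics are computed per subject and averaged across
the group before applying the rule; the partition and participation behind
hub *typing* come from a group-representative network (the group-mean
adjacency binarized at its own minimum density). Hubs with `P > 0.30` are
*connector* hubs, the rest *provincial* (the Guimerà–Amaral cartographic
cutoff; the study cites the taxonomy without printing the threshold, and
every hub it reports has `P ≥ 0.44`, comfortably above the cutoff).

## Cognition scoring

Five test scores (RAVLT A1/A6, CTMT trails 1/5, COWA) are z-normalized
against the control group's mean and SD per test; timed tests are
sign-flipped so negative z always means worse performance. By default the
reference is timepoint-matched (controls measured at the same visit);
a baseline-only reference is available since the study does not state
which it used. The ICCTF impairment rule is applied per timepoint —
impaired iff at least two z ≤ −1.5 or at least one z ≤ −2.0, thresholds
inclusive — and longitudinally: impaired at baseline and year 1 is
*persistent*, impaired at year 1 only is *late onset*, and impairment
present only at baseline falls outside both definitions and maps to an
unimpaired outcome (flagged `resolved`). Incidence is compared between
groups with the Pearson chi-squared test on the 2×2 table, *without*
continuity correction — the uncorrected statistic is the one that
reproduces X² = 6.56 for 17/31 vs 11/43; the Yates-corrected variant is
available behind a flag.

## Prediction

**Feature sets.** Model 1: six patient/medical covariates (age, education
years, ordinal stage, minority status, menopausal status, CAD total).
Model 2: covariates plus the clustering coefficients of three a-priori
regions. Model 3: covariates plus clustering for all regions (96 features
at the default parcellation).

**Nested scheme.** Patients are split 75/25 with stratified class
sampling; per class the hold-out count is the fractional count rounded to
the nearest integer, with exact halves resolved by a seeded coin (for a
17/14 class split this yields hold-out sizes of 7 or 8). The hold-out is
untouched until final evaluation. On the training set, recursive feature
elimination runs across 100 seeded random A/B partitions: a forest fit on
A ranks features by Gini importance, and each candidate subset size is
scored by predicting every held-out B member from a forest refit on A
restricted to the top-ranked features. The candidate ladder is an
exhaustive countdown `p, p−1, …, 1` for `p ≤ 20` and geometric halving for
larger `p` (tractability on ~100-feature models). The size with the best
mean accuracy across partitions wins, ties toward fewer features, and the
final feature set is the top of a ranking refit on the whole training set.

The study's "bootstrapping the features with replacement" phrasing is read
as standard random-forest mechanics — a bootstrap of *samples* per tree
plus `√p` features tried per split — matching the implementation lineage
it cites; a literal feature bootstrap is non-standard. The final
classifier is a 500-tree forest with out-of-bag error estimation
(scikit-learn). Inner RFE forests use 30 ranking / 15 scoring trees: on
one CPU this keeps a 100-partition model-3 RFE near half a minute, and in
benchmarks the selected subsets agreed with much larger inner forests.
The inner "leave-one-out cross-validation across 100 random partitions"
wording is ambiguous; scoring every B member individually from the A-fit
forest is the implemented reading.

**Evaluation.** Hold-out accuracy, sensitivity (impaired = positive),
specificity, ROC AUC from forest vote fractions (midrank ties), and a
two-sided exact binomial test against chance 0.5 in the minimum-likelihood
convention — this reproduces all three reported p-values (0.453 for 5/7,
0.070 for 7/8, 0.0078 ≈ 0.008 for 8/8), which also pins the chance level
at 0.5. AUCs of competing models are compared with a paired bootstrap over
the shared hold-out subjects, resampled within class so both classes stay
represented: `z = ΔAUC / SD_boot(ΔAUC)`, two-sided normal p. All models
share one hold-out split so the comparison is paired.

**Regression.** Individual year-1 z-scores per test are regressed on the
selected brain features with a 500-tree regression forest (`mtry = p/3`,
the regression default of the cited lineage). R² comes from out-of-bag
predictions; adjusted R² is `1 − (1−R²)(n−1)/(n−p−1)`, with a p-value from
the implied F statistic (the study does not state how its regression
p-values were computed; this is the documented choice). Importances are
percent increase in OOB MSE under per-feature permutation, computed
tree-wise on each tree's out-of-bag sample.

## Synthetic cohorts

The generator emulates what the pipeline needs and nothing more:

* **Networks.** Edge weights are Gaussian around a within-module mean
  (0.5) or between-module mean (0.2) with SD 0.12, clipped to [−1, 1];
  modules are contiguous blocks (5 by default). This is the simplest model
  with the block structure the modularity analysis assumes; it does not
  attempt BOLD realism, spatial autocorrelation, or distance-dependent
  connectivity.
* **Planted deficit.** For patients whose hidden outcome is impaired, the
  weights among each designated predictive region's minimum-density
  neighbors are scaled by `1 − clustering_effect`. Down-weighting
  neighbor–neighbor edges (not the region's own edges) lowers `C_i` while
  approximately preserving `k_i`. Five predictive regions, one per module,
  are the default.
* **Cognition.** Controls draw all scores from fixed per-test reference
  distributions (nominal instrument scales; immaterial downstream because
  of z-scoring — floor effects are not modeled, so extreme synthetic raw
  scores can leave the instrument's physical range). Impaired subjects are
  shifted down on two randomly chosen tests at the timepoints their
  category dictates (persistent: all visits; late onset: follow-up only).
  The late-onset share among impaired patients defaults to 0.41.
* **Calibration.** The impairment shift is specified in *realized*
  control-SD units. Impaired controls sit inside the normalization sample,
  so a raw shift `d` inflates the per-test reference SD to
  `s = √(1 + f(1−f)d²)` with `f` the shifted fraction of control scores;
  the generator solves `d = δ·s` self-consistently, giving
  `d = δ/√(1 − f(1−f)δ²)`. With that convention a designated subject trips
  the ICCTF rule almost surely and an undesignated one almost never, so
  classified incidence equals the designation probability and the
  configured rates (0.55 patients / 0.26 controls) are realized directly.
  The observed separation saturates at `1/√(f(1−f))`; infeasible requests
  are capped at 95% of that bound. With `δ = 0` the correction vanishes
  and patient and control classified rates collapse to the same background.
* **Covariates.** Age ~ U[34, 65], education, ordinal stage with
  probabilities (0.16, 0.65, 0.19), binary minority and menopause, CAD
  total. By default they carry no outcome information; optional log-odds
  weights couple them to the outcome for sensitivity studies.
* **Seeding.** One global seed expands to per-subject substreams keyed by
  (group, within-group index, purpose), so growing the cohort never
  reshuffles existing subjects, and identical config + seed reproduces the
  cohort bit-for-bit.

**What passing tests show — and don't.** The end-to-end property tests run
cohorts of 120 patients / 80 controls with `clustering_effect = 0.5` and a
3-SD cognitive effect: the model-3 pipeline must reach median hold-out AUC
≥ 0.9 over 10 seeds with the planted regions ranked among the top-10 Gini
importances, and must stay within the chance binomial band when the
planted effect is zero. This demonstrates that the pipeline recovers a
known signal and does not hallucinate one — it does not certify the
study's reported accuracies (100%/88%/71%), which depend on the
non-deposited clinical data. Likewise the per-test regression adjusted R²
on synthetic cohorts is intrinsically small (~0.1): the generator assigns
each impaired subject's deficit to two random tests, so any single test's
score is only weakly coupled to the brain features; the regression
machinery itself is validated separately on noiseless and null targets.

## Numerical choices and degenerate inputs

* All-zero matrices cannot be binarized (explicit error); zero-variance
  metrics mark no hubs; zero control SD raises naming the test; constant
  outcomes and constant regression targets raise.
* A single-class hold-out leaves AUC undefined (reported missing, with a
  warning) rather than raising.
* Chi-squared requires a non-degenerate 2×2 margin; the exact binomial
  test requires `n ≥ 1`.
* Problem sizes in tests (cohort sizes, partition counts, inner tree
  counts) are the package's own defaults for desk-scale verification;
  they are stated where they deviate from the analysis defaults.

## Known limitations

* The generator's edge-weight model has no negative-correlation structure
  beyond Gaussian tails and no subject-level network covariates (motion,
  age effects on topology).
* Hub typing depends on the group-representative partition; on weakly
  modular group-mean networks module identity can be unstable even though
  each subject's metrics are not.
* The RFE reading of the study's inner cross-validation is one of several
  defensible interpretations; the choice is documented above and isolated
  in `rfe_select`, so alternatives are easy to slot in.
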