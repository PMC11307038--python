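# Methods

`mirseparate` reimplements, as a tested pipeline over synthetic cohorts, a
small-cohort extracellular-miRNA biomarker analysis: discriminating LRRK2
mutation carriers (LRRK2_MC) from sporadic Parkinson's disease patients
(sPD) using RT-qPCR panels measured in plasma and CSF, with healthy
controls (HC) serving only as the fold-change reference.

## Ct processing

**Interplate calibration.** Every plate carries UniSpike 3 wells at a fixed
nominal input. The calibration factor of plate *p* is

    CF_p = mean(UniSpike-3 Ct on plate p) − mean(all UniSpike-3 Ct pooled over plates)

and every Ct on plate *p* is replaced by `Ct − CF_p`. Only detected spike
wells enter the means. Two consequences worth noting:

* *Identifiability.* The procedure removes relative plate differences
  only. Adding shifts `c_p` to whole plates moves every calibrated value
  by the pooled-spike-weighted mean of the shifts — one global constant,
  indistinguishable from a baseline change and cancelled exactly by the
  per-individual global-mean ΔCt step. Invariance tests therefore draw
  arbitrary shifts and centre them to pooled-weighted mean zero.
* *Idempotence.* Recalibrating an already-calibrated dataset yields
  factors of zero and an unchanged matrix.

**Censoring and retention.** Ct values strictly above 40 are treated as
unspecific and set missing (exactly 40.0 is retained). A feature missing
in strictly more than one individual is dropped, applied per fluid
independently. Missing-token dialects accepted on input: `undetected`,
`Undetermined`, an empty cell, or a sentinel Ct ≥ 99.

**Missingness balance.** Whether dropout hits the groups evenly is checked
with an exact conditional test: given the total number of missing samples
for a feature, the per-group missing counts follow a multivariate
hypergeometric law under the null; the p-value sums all splits at most as
likely as the observed one. This is the r×2 generalization of Fisher's
exact test (and reduces to it for two groups; the reduction is verified
against `scipy.stats.fisher_exact` in the tests). The check is
report-only — no feature is auto-excluded by it — because it mirrors a
confirmation step, not a filter.

## Fold changes (global-mean 2^−ΔΔCt)

For each individual, `mean_ct` is the average Ct over that individual's
*detected* miRNAs (computed after filtering; a config switch allows the
pre-filter alternative). Then per miRNA *n*:

    ΔCt_n     = Ct_n − mean_ct
    ΔΔCt_n    = ΔCt_n − mean(ΔCt_n over HC samples)
    fc        = 2^(−ΔΔCt),   log2fc = −ΔΔCt  (computed analytically)

Missing inputs propagate to missing outputs. By construction the HC group
has mean log2fc 0 (geometric-mean fc 1) for every miRNA, each individual's
fold changes are invariant to sample-wide Ct shifts, and a planted group
shift of δ cycles on one assay appears as a log2fc difference of
−δ·(1 − 1/m) on a fully retained m-assay panel (the global-mean
renormalization; the synthetic generator's ground truth carries the exact
expectation).

## Statistical readouts

* **t-tests** on log2fc per miRNA, pooled-variance Student's t with
  df = n₁+n₂−2 (Welch behind a flag). The significance threshold is α/m
  with m the number of tests actually performed; display rounding to four
  decimals is reporting-only. No FDR procedure, matching the design being
  reproduced. The printed df convention of the original analysis could
  not be inferred from group sizes and is not replicated.
* **ROC** for markers passing the threshold: rank-statistic AUC, operating
  point maximizing Youden's J (ties toward higher sensitivity), and a
  DeLong placement-value 95% CI truncated to [0, 1]. Orientation is
  chosen automatically so the AUC is ≥ 0.5 (as `pROC`'s `direction="auto"`
  does); the folded statistic is therefore biased above 0.5 under the
  null, and null-calibration tests use the unfolded rank statistic.
* **PCA** on calibrated Ct, mean-imputed per feature, centred but not
  variance-scaled. Deterministic sign convention: the largest-magnitude
  loading of each component is made positive. Group separation is scored
  by nearest group centroid in PC1 (or PC1+PC2) with distance ties to the
  positive class; the original decision rule is unstated, so this is a
  documented choice (a best-threshold-on-PC1 variant would also be
  defensible). Outlier screen: robust z on PC1/PC2 scores
  (MAD × 1.4826, flag beyond k = 3); report-only, removal is an explicit
  pipeline option, after which the retention filter is re-applied on the
  reduced cohort.
* **Integration.** All CSF-panel × CSF-panel-in-plasma Ct pairs (the full
  grid — the reading consistent with a selected-pair count larger than
  the panel) are Pearson-correlated on pairwise-complete samples, gated
  at two-tailed p < 0.05 with no multiplicity correction (a
  feature-construction heuristic, not an inference). Selected pairs become
  multiplied features `Ct_CSF × Ct_plasma` on raw calibrated values;
  imputation is left to each consumer.
* **LASSO-LOOCV.** L1-penalized logistic regression; features standardized
  inside each training fold; penalty strength chosen by inner
  stratified CV (default 5-fold, shrunk to the smallest class when
  needed) over a logarithmic grid — all inside the leave-one-out loop, so
  nothing leaks from the held-out sample. Threshold 0.5 on predicted
  probability, ties to the positive class (LRRK2_MC throughout). If the
  penalty collapses a fold's model entirely (liblinear also shrinks the
  intercept toward zero), the fold predicts the training majority. The
  final all-sample fit's nonzero coefficients double as feature selection.
* **Random forest.** 100 independent forests of 200 bootstrap trees,
  √p features per split. Each sample is predicted by majority vote of its
  out-of-bag trees; per-model sensitivity/specificity are summarized as
  mean ± 1.96·sd/√100 (the across-model spread is consistent with the
  near-degenerate CIs such ensembles report). Proximity = fraction of
  trees co-locating a sample pair in a terminal node, averaged over
  models. Importance is the node-weighted mean decrease in Gini impurity
  (scikit-learn's convention, averaged over models); it differs from R
  `randomForest`'s unnormalized per-tree sum by a constant factor, so
  rankings — the only use here — agree. Missing values are imputed by
  iterated proximity-weighted averages of observed values (5 rounds), the
  forest-based imputation scheme; imputed values are convex combinations
  of observations.
* **Consensus.** Top-5 by t-test p, top-5 by |PC1 loading|, top-5 by Gini
  decrease, plus all LASSO-retained features; ties always break by
  feature id, making selection a pure function of its inputs. The
  promoted tier is "selected by ≥ 2 methods"; pairwise intersection sizes
  form the chord-diagram adjacency.

All randomness flows from one master seed; per-stage seeds are derived by
SHA-256 hashing of (seed, stage name), and the random-forest ensemble
derives per-model streams from `numpy.random.SeedSequence`. Identical
config + seed gives byte-identical output tables.

## The synthetic cohort generator

No patient-level data are distributed with the original study, so the
generator is a first-class module that emulates the *structure* of the
data; every downstream stage is exercised against it.

Model: well Ct = baseline + assay offset + planted group shift + plate
offset + well noise (+ CSF penalty, + outlier shift), all additive
Gaussian on the Ct scale — the standard qPCR assumption, which makes
log-scale effects additive. Values above the censoring limit are recorded
as undetected. Each sample-fluid panel occupies one plate (panels never
span plates) and carries UniSpike 2/3/4/6 wells plus an undetected blank.

Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| cohort | 10 LRRK2_MC / 10 sPD / 11 HC | study group sizes; 4/10 carriers asymptomatic |
| panel | 91 assays per fluid | study panel width |
| baseline Ct | 33 ± 4 (assay spread) | extracellular miRNAs ride the detection limit |
| low-abundance tier | 35% of panel, +8 Ct | abundance is bimodal; yields ~60/91 plasma retention |
| plate offset sd | 0.5 Ct | plausible interplate variation (not reported; configurable) |
| well noise sd | 0.5 Ct | stands in for technical *plus* biological variation; reproduces the reported within-group log2fc SDs (~0.5) |
| CSF penalty | +12 Ct | drives heavy CSF dropout (~10–15/91 retained) |
| CSF-detectable set | 11 named assays | the abundant subset exempt from the penalty, matching the CSF panel size |
| cross-fluid ρ | 0.5 | those assays share half their well noise across fluids, giving Pearson r near the reported 0.36–0.51 range |
| planted effects | 5 discriminatory miRNAs | Ct shifts solved so expected group-mean log2fc equals the reported means exactly (the solver inverts the global-mean renormalization) |

What the generator does **not** emulate: per-sample global abundance
variation (RNA yield), so the synthetic PC1 variance share is far below a
real cohort's ~77% — group separation in PC space here comes from planted
shifts only; amplification-efficiency differences (the 2^−ΔΔCt base-2
assumption is exact by construction); heteroskedasticity near the
detection limit; and any correlation structure among null assays. Passing
tests therefore demonstrate correctness of the *procedures* and
recoverability of planted effects under the stated noise model, not
real-data performance. The planted sample-wide outlier shift is applied
to plasma only, mirroring the single-fluid outlier scenario it emulates;
because the global-mean ΔCt cancels sample-wide shifts, such an outlier
is visible to Ct-space PCA but invisible to fold changes — exactly the
behavior that motivates screening in Ct space.

## Numerical choices and degenerate inputs

Censoring uses strict `>`; retention uses strict `>` on the missing
count. Constant rows in z-scoring are emitted as zeros with a warning.
PCA requires a complete matrix and at least two samples; zero-variance
input is a hard error. Correlation pairs with fewer than three complete
samples are skipped with a flag. A miRNA with no detected HC value raises
a no-reference error naming the miRNA. Calibration with an all-undetected
UniSpike 3 plate raises an error naming the plate. p-value histograms use
right-closed bins so p = 1 lands in the last bin.

## Problem sizes used in tests

The test suite runs entirely on generated data: unit tests use 4–16
sample cohorts on 6–14-assay panels; the property suites use 200
planted-effect panels and 500 null panels at the study scale
(9 vs 10 + 11 HC, 58 assays), 1000 random 5×6 fold-change matrices, 100
random calibration-shift cases, and ~100 single-forest runs. These sizes
were chosen so the statistical assertions have narrow Monte-Carlo bands
while the whole suite stays comfortably runnable on a laptop.

## Known limitations

* The detection-power clause of the planted-effect recovery suite cannot
  be met under the stated conditions: at within-group log2fc SD ≈ 0.5,
  n = 9 vs 10 and threshold α/58, the noncentral-t power for a 1.0 log2fc
  difference is ≈ 0.61. The corresponding assertion is left failing with
  that analysis in its message rather than weakened; the recovery clause
  (±0.15) passes.
* LASSO-LOOCV on permutation nulls is systematically pessimistic (the
  held-out sample's label weakens its own class in the training fold), so
  permutation checks assert that chance lies inside the 95% simulation
  band rather than that the mean equals 0.5.
* The consensus lists on default synthetic cohorts contain the planted
  markers plus noise features; the original study's exact Table-2 lists
  are reproduced only as overlap arithmetic on the printed selections,
  since the underlying cohort data are not available.
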