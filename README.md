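# mirseparate

Can the extracellular miRNA signature in blood plasma tell a *LRRK2*
mutation carrier from a sporadic Parkinson's disease patient? Answering
that question from RT-qPCR panel data takes a chain of small, easily
miscoded steps: spike-in interplate calibration, detection-limit
censoring, global-mean 2^−ΔΔCt fold changes against a healthy-control
reference, Bonferroni-thresholded t-tests, PCA on calibrated Ct values,
cross-biofluid feature fusion, LASSO and random-forest classification,
and a consensus over the per-method marker selections.

`mirseparate` implements that entire analysis as a tested Python library
with a CLI and numbered analysis drivers, together with a synthetic-cohort
generator that reproduces the data *structure* such a study produces
(three groups, dual-fluid 91-plex panels, per-plate Ct offsets, UniSpike
2/3/4/6 controls, blank wells, heavy CSF dropout at Ct > 40) so that every
stage is verifiable end to end without any patient data. It is aimed at
researchers analyzing small-cohort qPCR biomarker panels who want each
processing step reproducible, seeded and unit-tested.

## The model in brief

Ct is a log2 abundance scale (one cycle ≈ two-fold). For sample *i* and
miRNA *n* on plate *p*:

    Ct_cal   = Ct_raw − CF_p,   CF_p = mean(UniSp3 Ct on p) − mean(all UniSp3 Ct)
    ΔCt_n    = Ct_cal − mean_Ct_i            (mean over sample i's detected miRNAs)
    ΔΔCt_n   = ΔCt_n − mean ΔCt_n over HC
    fc = 2^(−ΔΔCt),  log2fc = −ΔΔCt

Ct > 40 is censored; features missing in more than one individual are
dropped per fluid. Group discrimination (LRRK2_MC vs sPD, carriers
positive) is then read out four ways — per-miRNA pooled-variance t-tests
at the α/m threshold, nearest-centroid separation in PC space,
L1-logistic regression under leave-one-out cross-validation, and 100
random forests of 200 trees scored on out-of-bag votes — and the
per-method top markers are intersected. CSF and plasma are fused by
Pearson-gating all CSF-panel Ct pairs (two-tailed p < 0.05) and
multiplying the paired Ct values into new features. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (seed 1). Step 01 writes raw plates; each later step
reads the previous step's tables from `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_calibrate_filter.py
python analysis/04_univariate.py
```

prints

```
cohort: {'HC': 11, 'LRRK2_MC': 10, 'sPD': 10}
8 plates, 5952 wells; censored: {'plasma': 643, 'CSF': 2343}
...
spike-in QC: 32/32 pass, 0 blank violations
calibration factors span -1.14 .. +0.62 Ct
CSF: 14/91 features retained, 17 wells censored, 1 missingness-balance flags
plasma: 66/91 features retained, 36 wells censored, 0 missingness-balance flags
...
plasma: 66 tests, threshold 0.0008, 10 below 0.05 uncorrected, significant after correction: miR-153-3p, miR-29c-3p, miR-148a-3p, miR-128-3p
  ROC miR-29c-3p: AUC 0.97 (95% CI 0.90-1.00), sens 100% / spec 90%
CSF: 14 tests, threshold 0.0036, 0 below 0.05 uncorrected, significant after correction: none
```

Reading this: the CSF panel collapses from 91 to 14 reliably detected
miRNAs (low CSF RNA abundance pushes most reactions past the Ct 40
detection limit), while plasma retains 66. In plasma, the planted
discriminatory miRNAs pass the corrected threshold 0.05/66 ≈ 0.0008 and
separate carriers from sporadic patients almost perfectly in ROC terms;
the CSF panel alone carries no group signal — the structure the pipeline
is built to expose. Later steps add PCA separation
(`05_pca.py`: PC1+PC2 nearest-centroid sensitivity 90%, specificity
100%), the cross-fluid gate (`06_integrate.py`: 11 of 196 pairs pass at
|r| 0.36–0.51), the classifiers (`07_classifiers.py`: LASSO-LOOCV
100%/100%; RF-OOB mean sensitivity 88.2%, 95% CI 86.8–89.6%) and the
consensus (`08_consensus.py`: all five planted miRNAs nominated by ≥ 2
methods).

The same pipeline is available as one call (`mirseparate run`) or
stage-by-stage subcommands (`simulate`, `calibrate`, `normalize`,
`univariate`, `pca`, `integrate`, `classify`, `consensus`), and as a
library:

```python
from mirseparate import RunConfig, run_pipeline
from mirseparate.synthetic import default_sim_config

result = run_pipeline(RunConfig(sim=default_sim_config(), seed=1, outdir="results/run"))
print(result.univariate["plasma"].significant)
```

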