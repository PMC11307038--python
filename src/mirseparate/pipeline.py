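"""End-to-end pipeline: ingest/simulate -> calibrate -> normalize -> analyze.

Stages run in the study's order: raw plates are spike-in calibrated,
censored and filtered per fluid; an optional PCA-based outlier screen can
remove flagged plasma samples (the panel is then re-filtered on the
reduced cohort); fold changes are computed against the healthy-control
reference; then the comparison groups are analyzed with per-miRNA t-tests,
PCA, cross-fluid integration, LASSO-LOOCV and a random-forest ensemble,
and the per-method selections are merged into a consensus.

Healthy controls enter only as the fold-change reference (and, optionally,
the PCA plots); every discrimination readout compares the two configured
groups. All randomness flows from the master seed; each stage derives its
own stream by stable hashing of (seed, stage name). Every intermediate
table is persisted under the output directory along with a manifest
(config, derived seeds, library versions, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import apply_calibration, censor_and_filter, compute_calibration_factors, spike_in_qc
from .classifiers import ClassifierReport, lasso_loocv, proximity_impute, rf_ensemble
from .config import RunConfig
from .consensus import ConsensusSelection, select_consensus
from .datatypes import CohortTable, CtMatrix
from .exceptions import PipelineStageError
from .integration import CorrelationGate, MultipliedMatrix, build_multiplied_features, cross_fluid_correlation
from .io import read_raw_plates, write_ground_truth, write_matrix, write_raw_plates, write_sample_sheet
from .multivariate import PcaModel, fit_pca, loading_rank, mean_impute, pc_classify, pca_outlier_screen
from .normalization import compute_fold_changes, row_zscores
from .synthetic import generate_cohort, simulate_raw_plates
from .univariate import group_ttests, pvalue_histogram, roc, ttest_matrix


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: stable hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was persisted."""

    config: RunConfig
    outdir: Path
    cohort: CohortTable
    matrices: dict  # fluid -> filtered CtMatrix
    fold_changes: dict  # fluid -> FoldChangeTable
    univariate: dict  # dataset name -> UnivariateResult
    roc_results: dict  # assay -> RocResult
    pca: dict  # dataset name -> PcaModel
    pc_classification: dict  # (dataset, dims) -> PcClassification
    outliers: list
    gate: CorrelationGate | None
    multiplied: MultipliedMatrix | None
    lasso: dict  # dataset name -> ClassifierReport
    rf: dict  # dataset name -> ClassifierReport
    consensus: dict  # dataset name -> ConsensusSelection
    ground_truth: object | None = None
    qc: dict = field(default_factory=dict)


def _manifest(config: RunConfig, outdir: Path, seeds: dict) -> None:
    import sklearn

    cfg = config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg, sort_keys=True)
    manifest = {
        "mirseparate_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "sklearn_version": sklearn.__version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "stage_seeds": seeds,
    }
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in ("simulate", "lasso", "rf", "impute")}
    _manifest(config, outdir, seeds)
    groups = config.groups
    stage = "ingest"
    try:
        # --- data ---------------------------------------------------------
        truth = None
        if config.sim is not None:
            stage = "simulate"
            sim = config.sim.with_(seed=seeds["simulate"])
            cohort = generate_cohort(sim)
            plates, truth = simulate_raw_plates(cohort, sim)
            write_raw_plates(plates, outdir / "raw_plates.csv")
            write_sample_sheet(cohort, outdir / "sample_sheet.csv")
            write_ground_truth(truth, outdir)
        else:
            plates, cohort = read_raw_plates(config.plates_path, config.samples_path)
        cohort.table.to_csv(outdir / "cohort.csv")

        # --- calibration & QC ---------------------------------------------
        stage = "calibrate"
        qc_spikes = spike_in_qc(plates, censor_ct=config.censor_ct)
        qc_spikes.spike_checks.to_csv(outdir / "spike_qc.csv", index=False)
        qc_spikes.blank_violations.to_csv(outdir / "blank_violations.csv", index=False)
        factors = compute_calibration_factors(plates)
        factors.factors.rename_axis("plate_id").to_csv(outdir / "calibration_factors.csv")
        calibrated = apply_calibration(plates, factors)

        stage = "censor_filter"
        matrices: dict[str, CtMatrix] = {}
        qc = {"spikes": qc_spikes}
        for fluid, matrix in calibrated.items():
            filtered, report = censor_and_filter(
                matrix, cohort, config.censor_ct, config.max_missing
            )
            matrices[fluid] = filtered
            qc[fluid] = report
            report.missing_by_group.to_csv(outdir / f"qc_missing_{fluid}.csv", index=False)

        # --- outlier screen (plasma) ---------------------------------------
        stage = "outlier_screen"
        outliers: list[str] = []
        if "plasma" in matrices and len(matrices["plasma"].values) >= 3:
            screen_model = fit_pca(mean_impute(matrices["plasma"]), n_components=2)
            outliers = pca_outlier_screen(screen_model, k_sd=3.0)
            if outliers and config.remove_outliers:
                reduced = calibrated["plasma"].drop_samples(outliers)
                matrices["plasma"], qc["plasma"] = censor_and_filter(
                    reduced, cohort, config.censor_ct, config.max_missing
                )
        (outdir / "outliers.json").write_text(
            json.dumps({"flagged": outliers, "removed": bool(outliers) and config.remove_outliers})
        )
        for fluid, m in matrices.items():
            write_matrix(m, outdir / f"matrix_{fluid}_filtered.csv")

        # --- fold changes ---------------------------------------------------
        stage = "normalize"
        fold_changes = {}
        for fluid, m in matrices.items():
            fc = compute_fold_changes(m, cohort)
            fold_changes[fluid] = fc
            fc.table.to_csv(outdir / f"fold_changes_{fluid}.csv", index=False)
            heat = row_zscores(fc.wide("log2fc").T)
            heat.to_csv(outdir / f"heatmap_log2fc_{fluid}.csv")

        # --- univariate -----------------------------------------------------
        stage = "univariate"
        univariate = {}
        roc_results = {}
        for fluid, fc in fold_changes.items():
            res = group_ttests(fc, cohort, groups, config.alpha)
            univariate[fluid] = res
            res.table.to_csv(outdir / f"ttests_{fluid}.csv", index=False)
            pvals = res.table.loc[~res.table["skipped"], "p"]
            pvalue_histogram(pvals).to_csv(outdir / f"pvalue_hist_{fluid}.csv", index=False)
        if "plasma" in univariate:
            wide = fold_changes["plasma"].wide("log2fc")
            for assay in univariate["plasma"].significant:
                sub = [s for g in groups for s in cohort.samples_in(g) if s in wide.index]
                vals = wide.loc[sub, assay]
                labels = (cohort.groups_of(sub) == "LRRK2_MC").astype(int)
                rr = roc(vals.to_numpy(), labels.to_numpy())
                roc_results[assay] = rr
                rr.sweep.to_csv(outdir / f"roc_{assay.replace('/', '_')}.csv", index=False)

        # --- PCA ------------------------------------------------------------
        stage = "pca"
        pca_models = {}
        pc_cls = {}
        if "plasma" in matrices:
            pca_samples = [s for g in groups for s in cohort.samples_in(g)]
            if config.include_hc_pca:
                pca_samples += cohort.samples_in("HC")
            pca_samples = [s for s in pca_samples if s in matrices["plasma"].values.index]
            sub = matrices["plasma"].subset_samples(pca_samples)
            model = fit_pca(mean_impute(sub))
            pca_models["plasma"] = model
            model.scores.to_csv(outdir / "pca_scores_plasma.csv")
            model.loadings.to_csv(outdir / "pca_loadings_plasma.csv")
            pd.Series(model.variance_ratio, name="variance_ratio").to_csv(
                outdir / "pca_variance_plasma.csv", index_label="component"
            )
            for dims in (1, 2):
                pc_cls[("plasma", dims)] = pc_classify(model, cohort, groups, dims)

        # --- integration ----------------------------------------------------
        stage = "integrate"
        gate = None
        multiplied = None
        if "CSF" in matrices and "plasma" in matrices:
            gate = cross_fluid_correlation(matrices["CSF"], matrices["plasma"], config.alpha)
            gate.pairs.to_csv(outdir / "correlation_gate.csv", index=False)
            multiplied = build_multiplied_features(gate, matrices["CSF"], matrices["plasma"])
            multiplied.values.to_csv(outdir / "multiplied_features.csv", index_label="sample_id")

        # --- classifiers ----------------------------------------------------
        stage = "classify"
        lasso_reports: dict[str, ClassifierReport] = {}
        rf_reports: dict[str, ClassifierReport] = {}
        datasets: dict[str, pd.DataFrame] = {}
        if "plasma" in matrices:
            comp = [s for g in groups for s in cohort.samples_in(g)]
            comp = [s for s in comp if s in matrices["plasma"].values.index]
            datasets["plasma"] = matrices["plasma"].values.loc[comp]
        if multiplied is not None and not multiplied.is_empty:
            comp = [s for g in groups for s in cohort.samples_in(g)]
            comp = [s for s in comp if s in multiplied.values.index]
            datasets["multiplied"] = multiplied.values.loc[comp]
            mult_t = ttest_matrix(datasets["multiplied"], cohort, groups, config.alpha)
            univariate["multiplied"] = mult_t
            mult_t.table.to_csv(outdir / "ttests_multiplied.csv", index=False)
            mult_vals = datasets["multiplied"]
            mult_model = fit_pca(mult_vals.fillna(mult_vals.mean(axis=0, skipna=True)))
            pca_models["multiplied"] = mult_model
            for dims in (1, 2):
                pc_cls[("multiplied", dims)] = pc_classify(mult_model, cohort, groups, dims)
        for name, feats in datasets.items():
            labels = cohort.groups_of(feats.index)
            mean_imputed = feats.fillna(feats.mean(axis=0, skipna=True))
            lasso_reports[name] = lasso_loocv(
                mean_imputed, labels, seed=seeds["lasso"], inner_cv=config.lasso_inner_cv
            )
            prox_imputed = proximity_impute(
                feats, labels, seed=seeds["impute"], n_trees=config.n_trees
            )
            rf_reports[name] = rf_ensemble(
                prox_imputed,
                labels,
                n_models=config.n_models,
                n_trees=config.n_trees,
                seed=seeds["rf"],
            )
            lasso_reports[name].predictions.to_csv(
                outdir / f"lasso_predictions_{name}.csv", index=False
            )
            lasso_reports[name].feature_weights.rename_axis("assay_id").to_csv(
                outdir / f"lasso_weights_{name}.csv"
            )
            rf_reports[name].per_model.to_csv(outdir / f"rf_per_model_{name}.csv", index=False)
            rf_reports[name].importances.rename_axis("assay_id").to_csv(
                outdir / f"rf_importances_{name}.csv"
            )
            rf_reports[name].proximity.to_csv(outdir / f"rf_proximity_{name}.csv")

        # --- consensus ------------------------------------------------------
        stage = "consensus"
        consensus = {}
        for name in datasets:
            if name in univariate and name in pca_models:
                sel = select_consensus(
                    univariate[name],
                    pca_models[name],
                    rf_reports[name],
                    lasso_reports[name],
                    k=config.k_consensus,
                )
                consensus[name] = sel
                rows = [
                    {"method": m, "rank": i + 1, "assay_id": a}
                    for m, feats in sel.lists.items()
                    for i, a in enumerate(feats)
                ]
                pd.DataFrame(rows).to_csv(outdir / f"consensus_lists_{name}.csv", index=False)
                sel.adjacency.to_csv(outdir / f"consensus_adjacency_{name}.csv")

        # --- summary --------------------------------------------------------
        stage = "summary"
        summary = _summary_table(
            matrices, univariate, roc_results, pca_models, pc_cls, gate, lasso_reports, rf_reports, consensus
        )
        summary.to_csv(outdir / "summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc

    return PipelineResult(
        config=config,
        outdir=outdir,
        cohort=cohort,
        matrices=matrices,
        fold_changes=fold_changes,
        univariate=univariate,
        roc_results=roc_results,
        pca=pca_models,
        pc_classification=pc_cls,
        outliers=outliers,
        gate=gate,
        multiplied=multiplied,
        lasso=lasso_reports,
        rf=rf_reports,
        consensus=consensus,
        ground_truth=truth,
        qc=qc,
    )


def _summary_table(matrices, univariate, roc_results, pca_models, pc_cls, gate, lasso, rf, consensus):
    rows = []

    def add(name, value):
        rows.append({"quantity": name, "value": value})

    for fluid, m in matrices.items():
        add(f"n_features_{fluid}", m.values.shape[1])
        add(f"n_samples_{fluid}", m.values.shape[0])
    for name, res in univariate.items():
        add(f"n_tests_{name}", res.m)
        add(f"threshold_{name}", res.threshold)
        add(f"n_significant_{name}", len(res.significant))
        if res.m:
            add(f"min_p_{name}", float(res.table["p"].min()))
    for assay, rr in roc_results.items():
        add(f"auc_{assay}", rr.auc)
    for name, model in pca_models.items():
        for j, v in enumerate(model.variance_ratio[:2]):
            add(f"pc{j + 1}_variance_{name}", float(v))
    for (name, dims), cls in pc_cls.items():
        add(f"pc{dims}_sensitivity_{name}", cls.sensitivity)
        add(f"pc{dims}_specificity_{name}", cls.specificity)
    if gate is not None:
        add("n_selected_pairs", gate.n_selected)
    for name, rep in lasso.items():
        add(f"lasso_sensitivity_{name}", rep.sensitivity)
        add(f"lasso_specificity_{name}", rep.specificity)
        add(f"lasso_n_retained_{name}", len(rep.retained_features))
    for name, rep in rf.items():
        add(f"rf_mean_sensitivity_{name}", rep.sensitivity)
        add(f"rf_mean_specificity_{name}", rep.specificity)
    for name, sel in consensus.items():
        add(f"consensus_multi_method_{name}", len(sel.multi_method))
    return pd.DataFrame(rows)
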