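"""Group prediction: LASSO-LOOCV and the out-of-bag random-forest ensemble.

Runs both classifiers on the plasma Ct features and on the multiplied
cross-fluid features (if any pairs passed the gate). LASSO uses mean
imputation; the forest uses proximity-weighted imputation. Writes
per-fold/per-model predictions, feature weights, Gini importances and
proximity matrices.
"""

import warnings
from pathlib import Path

import pandas as pd

from mirseparate import lasso_loocv, proximity_impute, rf_ensemble
from mirseparate.io import read_matrix, read_sample_sheet
from mirseparate.pipeline import stage_seed

DATA = Path("results/data")
CAL = Path("results/calibrated")
INT = Path("results/integration")
OUT = Path("results/classifiers")
SEED = 1


def run_dataset(name, features, cohort):
    comp = [s for g in ("LRRK2_MC", "sPD") for s in cohort.samples_in(g) if s in features.index]
    feats = features.loc[comp]
    labels = cohort.groups_of(comp)

    lasso = lasso_loocv(
        feats.fillna(feats.mean(axis=0)), labels, seed=stage_seed(SEED, "lasso")
    )
    lasso.predictions.to_csv(OUT / f"lasso_predictions_{name}.csv", index=False)
    lasso.feature_weights.rename_axis("assay_id").to_csv(OUT / f"lasso_weights_{name}.csv")
    print(
        f"{name}: LASSO-LOOCV sens {lasso.sensitivity:.1%} spec {lasso.specificity:.1%}; "
        f"retained {', '.join(lasso.retained_features) or 'none'}"
    )

    complete = proximity_impute(feats, labels, seed=stage_seed(SEED, "impute"))
    rf = rf_ensemble(complete, labels, n_models=100, n_trees=200, seed=stage_seed(SEED, "rf"))
    rf.per_model.to_csv(OUT / f"rf_per_model_{name}.csv", index=False)
    rf.importances.rename_axis("assay_id").to_csv(OUT / f"rf_importances_{name}.csv")
    rf.proximity.to_csv(OUT / f"rf_proximity_{name}.csv")
    s_ci, p_ci = rf.sensitivity_ci, rf.specificity_ci
    print(
        f"{name}: RF-OOB mean sens {rf.sensitivity:.1%} "
        f"(95% CI {s_ci[0]:.1%}-{s_ci[1]:.1%}), mean spec {rf.specificity:.1%} "
        f"(95% CI {p_ci[0]:.1%}-{p_ci[1]:.1%}); "
        f"top Gini: {', '.join(rf.top_importance(5))}"
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_sample_sheet(DATA / "sample_sheet.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plasma = read_matrix(CAL / "matrix_plasma_filtered.csv", "plasma")
        run_dataset("plasma", plasma.values, cohort)
        mult = pd.read_csv(INT / "multiplied_features.csv", index_col="sample_id")
        if mult.shape[1] > 0:
            run_dataset("multiplied", mult, cohort)
        else:
            print("multiplied: no gated pairs, skipped")


if __name__ == "__main__":
    main()
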