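"""PCA on calibrated plasma Ct values: separation, outliers, loadings.

Mean-imputes the filtered plasma matrix, fits the centered (unscaled)
decomposition for the two comparison groups, classifies samples by
nearest group centroid on PC1 and PC1+PC2, screens for outliers, and
ranks features by |PC1 loading|.
"""

from pathlib import Path

import pandas as pd

from mirseparate import fit_pca, loading_rank, mean_impute, pc_classify, pca_outlier_screen
from mirseparate.io import read_matrix, read_sample_sheet

DATA = Path("results/data")
CAL = Path("results/calibrated")
OUT = Path("results/pca")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_sample_sheet(DATA / "sample_sheet.csv")
    matrix = read_matrix(CAL / "matrix_plasma_filtered.csv", "plasma")

    groups = ("LRRK2_MC", "sPD")
    keep = [s for g in groups for s in cohort.samples_in(g) if s in set(matrix.sample_ids)]
    model = fit_pca(mean_impute(matrix.subset_samples(keep)))
    model.scores.to_csv(OUT / "scores.csv")
    model.loadings.to_csv(OUT / "loadings.csv")
    pd.Series(model.variance_ratio, name="variance_ratio").to_csv(
        OUT / "variance.csv", index_label="component"
    )
    print(f"PC1 {model.variance_ratio[0]:.1%} / PC2 {model.variance_ratio[1]:.1%} of variance")
    for dims in (1, 2):
        cls = pc_classify(model, cohort, groups, dims)
        print(f"  {cls.rule}: sensitivity {cls.sensitivity:.0%}, specificity {cls.specificity:.0%}")

    flagged = pca_outlier_screen(fit_pca(mean_impute(matrix), n_components=2))
    print(f"outlier screen (all samples): {', '.join(flagged) or 'none flagged'}")

    top = loading_rank(model, component=1, k=5)
    pd.Series(top, name="assay_id").to_csv(OUT / "pc1_top_loadings.csv", index_label="rank")
    print(f"top-5 |PC1 loading|: {', '.join(top)}")


if __name__ == "__main__":
    main()
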