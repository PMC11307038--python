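"""Consensus marker selection across the four plasma analyses.

Merges the top-5 t-test, top-5 |PC1 loading| and top-5 Gini features with
the LASSO-retained set, and reports the pairwise overlaps and the markers
nominated by at least two methods.
"""

from pathlib import Path

import pandas as pd

from mirseparate import overlap_sets

UNI = Path("results/univariate")
PCA = Path("results/pca")
CLF = Path("results/classifiers")
OUT = Path("results/consensus")
K = 5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ttests = pd.read_csv(UNI / "ttests_plasma.csv")
    t_top = ttests.loc[~ttests["skipped"]].sort_values(["p", "assay_id"])["assay_id"].head(K).tolist()
    pca_top = pd.read_csv(PCA / "pc1_top_loadings.csv")["assay_id"].head(K).tolist()
    weights = pd.read_csv(CLF / "lasso_weights_plasma.csv", index_col="assay_id")["coef"]
    lasso_sel = sorted(weights.index[weights != 0.0])
    gini = pd.read_csv(CLF / "rf_importances_plasma.csv", index_col="assay_id").iloc[:, 0]
    rf_top = sorted(gini.index, key=lambda a: (-gini[a], a))[:K]

    sel = overlap_sets({"t_test": t_top, "pca": pca_top, "lasso": lasso_sel, "rf": rf_top})
    rows = [
        {"method": m, "rank": i + 1, "assay_id": a}
        for m, feats in sel.lists.items()
        for i, a in enumerate(feats)
    ]
    pd.DataFrame(rows).to_csv(OUT / "selections.csv", index=False)
    sel.adjacency.to_csv(OUT / "adjacency.csv")
    for method, feats in sel.lists.items():
        print(f"{method:>7}: {', '.join(feats) or '-'}")
    print(f"selected by >=2 methods: {', '.join(sel.multi_method) or 'none'}")


if __name__ == "__main__":
    main()
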