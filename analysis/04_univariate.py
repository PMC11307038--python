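"""Per-miRNA t-tests on log2fc with the alpha/m threshold, plus ROC.

Compares LRRK2 mutation carriers against sporadic PD in each fluid,
writes the ranked test tables and p-value histograms, and runs ROC
analysis for every miRNA passing the corrected threshold in plasma.
"""

from pathlib import Path

import pandas as pd

from mirseparate import group_ttests, pvalue_histogram, roc
from mirseparate.io import read_sample_sheet
from mirseparate.normalization import FoldChangeTable

DATA = Path("results/data")
FC = Path("results/fold_changes")
OUT = Path("results/univariate")


def load_fc(fluid):
    table = pd.read_csv(FC / f"fold_changes_{fluid}.csv")
    return FoldChangeTable(table, pd.Series(dtype=float), pd.Series(dtype=float), "HC", fluid)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_sample_sheet(DATA / "sample_sheet.csv")
    for fluid in ("plasma", "CSF"):
        res = group_ttests(load_fc(fluid), cohort)
        res.table.to_csv(OUT / f"ttests_{fluid}.csv", index=False)
        pvals = res.table.loc[~res.table["skipped"], "p"]
        pvalue_histogram(pvals).to_csv(OUT / f"pvalue_hist_{fluid}.csv", index=False)
        print(
            f"{fluid}: {res.m} tests, threshold {res.threshold:.4f}, "
            f"{int((pvals < 0.05).sum())} below 0.05 uncorrected, "
            f"significant after correction: {', '.join(res.significant) or 'none'}"
        )
        if fluid != "plasma":
            continue
        wide = load_fc(fluid).wide("log2fc")
        for assay in res.significant:
            sub = [s for g in ("LRRK2_MC", "sPD") for s in cohort.samples_in(g) if s in wide.index]
            labels = (cohort.groups_of(sub) == "LRRK2_MC").astype(int)
            rr = roc(wide.loc[sub, assay].to_numpy(), labels.to_numpy())
            rr.sweep.to_csv(OUT / f"roc_{assay}.csv", index=False)
            print(
                f"  ROC {assay}: AUC {rr.auc:.2f} "
                f"(95% CI {rr.auc_ci[0]:.2f}-{rr.auc_ci[1]:.2f}), "
                f"sens {rr.sensitivity:.0%} / spec {rr.specificity:.0%}"
            )


if __name__ == "__main__":
    main()
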