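"""Per-miRNA two-group comparisons, multiplicity threshold and ROC analysis.

The primary readout is an unpaired two-sample t-test on log2 fold changes
for each miRNA (pooled-variance Student's t with df = n1 + n2 - 2 by
default; Welch available behind a flag). Significance is judged against a
Bonferroni-style threshold alpha / m, where m counts the tests actually
performed. Markers that pass are followed up with ROC analysis: AUC via
the rank (Mann-Whitney) statistic, the operating point maximizing
Youden's J, and a DeLong 95% confidence interval for the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CohortTable
from .exceptions import ConfigError
from .normalization import FoldChangeTable


@dataclass
class UnivariateResult:
    """Per-miRNA test results plus the panel-level threshold."""

    table: pd.DataFrame  # sorted ascending by p; skipped assays at the end
    groups: tuple[str, str]
    alpha: float
    m: int
    threshold: float

    @property
    def significant(self) -> list[str]:
        sig = self.table[self.table["passed"].fillna(False).astype(bool)]
        return sig["assay_id"].tolist()

    def top_k(self, k: int = 5) -> list[str]:
        """Smallest-p features; ties broken by assay id for determinism."""
        tested = self.table[~self.table["skipped"]].copy()
        tested = tested.sort_values(["p", "assay_id"], kind="mergesort")
        return tested["assay_id"].head(k).tolist()


def corrected_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-style threshold alpha / m (display rounding is reporting-only)."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must lie in (0, 1]")
    return alpha / m


def group_ttests(
    fc_table: FoldChangeTable,
    cohort: CohortTable,
    groups: tuple[str, str] = ("LRRK2_MC", "sPD"),
    alpha: float = 0.05,
    welch: bool = False,
) -> UnivariateResult:
    """Unpaired t-test on log2fc per miRNA between two groups.

    miRNAs with fewer than two non-missing values in either group are
    skipped (flagged, excluded from the test count m).
    """
    return ttest_matrix(fc_table.wide("log2fc"), cohort, groups, alpha, welch)


def ttest_matrix(
    wide: pd.DataFrame,
    cohort: CohortTable,
    groups: tuple[str, str] = ("LRRK2_MC", "sPD"),
    alpha: float = 0.05,
    welch: bool = False,
) -> UnivariateResult:
    """Per-column unpaired t-test on an arbitrary samples x features matrix.

    Used both for log2fc values and for cross-fluid multiplied Ct
    features, which are compared on their raw scale.
    """
    for g in groups:
        if g not in set(cohort.table["group"]):
            raise ConfigError(f"group {g!r} not present in the cohort")
    in_matrix = set(wide.index)
    idx = {g: [s for s in cohort.samples_in(g) if s in in_matrix] for g in groups}
    rows = []
    for assay in wide.columns:
        x = wide.loc[idx[groups[0]], assay].dropna().to_numpy()
        y = wide.loc[idx[groups[1]], assay].dropna().to_numpy()
        skipped = len(x) < 2 or len(y) < 2
        rec = {
            "assay_id": assay,
            f"n_{groups[0]}": len(x),
            f"n_{groups[1]}": len(y),
            f"mean_{groups[0]}": x.mean() if len(x) else np.nan,
            f"sd_{groups[0]}": x.std(ddof=1) if len(x) > 1 else np.nan,
            f"mean_{groups[1]}": y.mean() if len(y) else np.nan,
            f"sd_{groups[1]}": y.std(ddof=1) if len(y) > 1 else np.nan,
            "skipped": skipped,
        }
        if skipped:
            rec.update({"t": np.nan, "df": np.nan, "p": np.nan})
        else:
            res = stats.ttest_ind(x, y, equal_var=not welch)
            df = len(x) + len(y) - 2 if not welch else float(res.df)
            rec.update({"t": float(res.statistic), "df": df, "p": float(res.pvalue)})
        rows.append(rec)
    table = pd.DataFrame(rows)
    m = int((~table["skipped"]).sum())
    if m == 0:
        raise ConfigError("no miRNA has enough values in both groups")
    threshold = corrected_threshold(alpha, m)
    table["passed"] = (table["p"] < threshold).astype("boolean")
    table.loc[table["skipped"], "passed"] = pd.NA
    table = table.sort_values(
        ["skipped", "p", "assay_id"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return UnivariateResult(table=table, groups=groups, alpha=alpha, m=m, threshold=threshold)


def pvalue_histogram(pvals, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of p-values over (0, 1]; counts sum to the number of tests."""
    p = np.asarray([v for v in pvals if not np.isnan(v)], dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins so p = 1 lands in the last bin and p > 0 is respected
    idx = np.clip(np.ceil(p * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


@dataclass
class RocResult:
    """Threshold sweep with AUC, Youden-optimal point and DeLong 95% CI."""

    sweep: pd.DataFrame  # threshold, sensitivity, specificity
    auc: float
    sensitivity: float
    specificity: float
    auc_ci: tuple[float, float]
    positive_high: bool = field(default=True)


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the Mann-Whitney AUC via placement values."""
    m, n = len(pos), len(neg)
    v10 = np.array([((x > neg).sum() + 0.5 * (x == neg).sum()) / n for x in pos])
    v01 = np.array([((pos > y).sum() + 0.5 * (pos == y).sum()) / m for y in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc(values, labels) -> RocResult:
    """ROC for one marker against binary labels (1 = positive class).

    If the positive class sits at lower marker values the marker is
    flipped (AUC is kept >= 0.5-oriented the way a single printed
    sensitivity/specificity pair implies). The operating point maximizes
    Youden's J = sensitivity + specificity - 1; ties go to the point with
    higher sensitivity. The AUC confidence interval uses the DeLong
    placement-value variance, truncated to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    pos, neg = values[labels == 1], values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ConfigError("both classes must be present for ROC analysis")

    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (len(pos) * len(neg))
    positive_high = auc >= 0.5
    if not positive_high:
        values = -values
        pos, neg = -pos, -neg
        auc = 1.0 - auc

    thresholds = np.concatenate(([np.inf], np.unique(values)[::-1]))
    rows = []
    for thr in thresholds:
        pred = values >= thr
        rows.append(
            {
                "threshold": thr,
                "sensitivity": (pred & (labels == 1)).sum() / len(pos),
                "specificity": (~pred & (labels == 0)).sum() / len(neg),
            }
        )
    sweep = pd.DataFrame(rows)
    j = sweep["sensitivity"] + sweep["specificity"] - 1.0
    best = sweep.loc[j == j.max()].sort_values("sensitivity", ascending=False).iloc[0]

    var = _delong_auc_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocResult(
        sweep=sweep,
        auc=float(auc),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        auc_ci=(float(ci[0]), float(ci[1])),
        positive_high=bool(positive_high),
    )
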