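"""PCA on calibrated Ct values: imputation, group separation, outlier screen.

Missing values are mean-imputed per feature (over all samples in the
matrix) before the fit. The decomposition centers but does not scale the
columns — Ct values are already on a common log2 scale, so variance
weighting by raw cycle spread is intentional. A deterministic sign
convention (the largest-magnitude loading of each component is made
positive) keeps loadings reproducible across runs and libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import CohortTable, CtMatrix, POSITIVE_GROUP
from .exceptions import ConfigError, DegenerateInputError
from .metrics import confusion_counts, sensitivity_specificity


def mean_impute(matrix: CtMatrix) -> CtMatrix:
    """Replace each missing cell by its feature's mean over detected values."""
    values = matrix.values
    if (values.notna().sum(axis=0) == 0).any():
        empty = values.columns[values.notna().sum(axis=0) == 0].tolist()
        raise DegenerateInputError(f"features with no detected value: {empty}")
    filled = values.fillna(values.mean(axis=0, skipna=True))
    return CtMatrix(filled, matrix.fluid)


@dataclass
class PcaModel:
    """Centered (unscaled) principal component decomposition.

    ``loadings`` is features x components and column-orthonormal;
    ``scores`` is samples x components with scores = centered data @
    loadings; ``variance_ratio`` the fraction of total variance per
    component, non-increasing.
    """

    feature_means: pd.Series
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(matrix: CtMatrix | pd.DataFrame, n_components: int | None = None) -> PcaModel:
    """Fit PCA on a complete samples x features matrix (CtMatrix or DataFrame)."""
    values = matrix.values if isinstance(matrix, CtMatrix) else matrix
    if values.isna().any().any():
        raise ConfigError("fit_pca requires a complete matrix; run mean_impute first")
    n, p = values.shape
    if n < 2:
        raise DegenerateInputError("PCA needs at least two samples")
    centered = values - values.mean(axis=0)
    if not (centered.to_numpy() != 0).any():
        raise DegenerateInputError("matrix has zero variance")
    max_rank = min(n - 1, p)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values.to_numpy())
    loadings = pca.components_.T  # features x components

    # Sign convention: largest-|loading| entry of each component positive.
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]

    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaModel(
        feature_means=values.mean(axis=0),
        loadings=pd.DataFrame(loadings, index=values.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class PcClassification:
    """Nearest-centroid assignment in a low-dimensional PC subspace."""

    rule: str
    predicted: pd.Series
    sensitivity: float
    specificity: float
    confusion: tuple[int, int, int, int]  # TP, FN, TN, FP


def pc_classify(
    model: PcaModel,
    cohort: CohortTable,
    groups: tuple[str, str] = (POSITIVE_GROUP, "sPD"),
    dims: int = 1,
) -> PcClassification:
    """Assign each sample of the two groups to the nearer group centroid.

    Euclidean distance in the first ``dims`` PC coordinates; distance ties
    go to the positive class. Sensitivity counts the positive group
    (LRRK2 carriers when present, else the first group given).
    """
    if dims not in (1, 2):
        raise ConfigError("dims must be 1 or 2")
    positive = POSITIVE_GROUP if POSITIVE_GROUP in groups else groups[0]
    cols = [f"PC{j + 1}" for j in range(dims)]
    labels = cohort.groups_of([s for s in model.scores.index if s in set(cohort.sample_ids)])
    labels = labels[labels.isin(groups)]
    if set(groups) - set(labels):
        raise ConfigError(f"groups missing from scores: {sorted(set(groups) - set(labels))}")
    pts = model.scores.loc[labels.index, cols]
    centroids = pts.groupby(labels).mean()
    d = {g: np.linalg.norm(pts - centroids.loc[g].to_numpy(), axis=1) for g in groups}
    other = [g for g in groups if g != positive][0]
    pred = np.where(d[positive] <= d[other], positive, other)
    predicted = pd.Series(pred, index=pts.index, name="predicted")
    tp, fn, tn, fp = confusion_counts(labels.to_numpy(), pred, positive)
    sens, spec = sensitivity_specificity(tp, fn, tn, fp)
    return PcClassification(
        rule=f"nearest centroid on {'+'.join(cols)} (ties -> {positive})",
        predicted=predicted,
        sensitivity=sens,
        specificity=spec,
        confusion=(tp, fn, tn, fp),
    )


def pca_outlier_screen(model: PcaModel, k_sd: float = 3.0) -> list[str]:
    """Samples whose PC1 or PC2 score is a robust outlier.

    A score is flagged when it deviates from the component median by
    strictly more than ``k_sd`` robust standard deviations (median
    absolute deviation x 1.4826). Report-only: removal is an explicit
    pipeline option, not automatic.
    """
    if len(model.scores) < 3:
        raise ConfigError("outlier screen needs at least three samples")
    flagged: set[str] = set()
    for col in [c for c in ("PC1", "PC2") if c in model.scores.columns]:
        s = model.scores[col]
        med = s.median()
        scale = 1.4826 * (s - med).abs().median()
        dev = (s - med).abs()
        flagged |= set(s.index[dev > k_sd * scale])
    return sorted(flagged)


def loading_rank(model: PcaModel, component: int = 1, k: int = 5) -> list[str]:
    """Top-k features by |loading| on one component (ties by feature id)."""
    col = f"PC{component}"
    mags = model.loadings[col].abs()
    order = sorted(mags.index, key=lambda a: (-mags[a], a))
    return order[: min(k, len(order))]
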