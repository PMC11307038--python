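"""Penalized-regression and random-forest group prediction.

Two classifiers mirror the study design for LRRK2-carrier vs sporadic-PD
discrimination on small cohorts:

* L1-penalized logistic regression, evaluated by leave-one-out
  cross-validation (LOOCV). Features are standardized inside each training
  fold and the penalty strength is chosen by inner cross-validation over a
  logarithmic grid, so no information from the held-out sample leaks into
  the fit. The sparsity of the final all-sample fit doubles as feature
  selection.
* A random-forest ensemble: ``n_models`` independent forests of
  ``n_trees`` bootstrap trees each. Sensitivity and specificity are read
  from out-of-bag (OOB) votes — each sample predicted only by the trees
  that did not see it — and summarized as the across-model mean with a
  normal-approximation 95% confidence interval. Each forest also yields a
  sample-pair proximity matrix (fraction of trees placing the pair in the
  same terminal node) and mean-decrease-in-Gini feature importances.

Proximity-weighted imputation iterates a forest fit with missing cells
replaced by proximity-weighted averages of observed values, the classic
forest-based imputation scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .datatypes import POSITIVE_GROUP
from .exceptions import ConfigError
from .metrics import confusion_counts, sensitivity_specificity

Z95 = 1.959963984540054


@dataclass
class ClassifierReport:
    """Per-fold / per-model predictions and aggregate discrimination metrics."""

    kind: str
    positive: str
    predictions: pd.DataFrame
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    per_model: pd.DataFrame | None = None
    feature_weights: pd.Series | None = None  # penalized-model coefficients
    importances: pd.Series | None = None  # mean decrease in Gini impurity
    proximity: pd.DataFrame | None = None
    flagged: list | None = None

    @property
    def retained_features(self) -> list[str]:
        """Nonzero-coefficient features of the final penalized fit."""
        if self.feature_weights is None:
            return []
        w = self.feature_weights
        return sorted(w.index[w != 0.0])

    def top_importance(self, k: int = 5) -> list[str]:
        """Top-k features by importance; ties broken by feature id."""
        if self.importances is None:
            return []
        imp = self.importances
        order = sorted(imp.index, key=lambda a: (-imp[a], a))
        return order[: min(k, len(order))]


def _seed_ints(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _check_inputs(features: pd.DataFrame, labels: pd.Series, positive: str):
    if features.isna().any().any():
        raise ConfigError("classifier features must be complete; impute first")
    labels = labels.loc[features.index]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ConfigError(f"need exactly two classes, got {classes}")
    if positive not in classes:
        positive = POSITIVE_GROUP if POSITIVE_GROUP in classes else classes[0]
    if min((labels == c).sum() for c in classes) < 2:
        raise ConfigError("both classes need at least two samples")
    return labels, positive


def lasso_loocv(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    positive: str = POSITIVE_GROUP,
    inner_cv: int = 5,
    Cs: np.ndarray | int = 20,
) -> ClassifierReport:
    """L1-logistic LOOCV: each sample predicted by a model fit on the rest.

    The held-out label is called positive when the predicted probability is
    at least 0.5. Folds whose training set loses a class are flagged and
    excluded from the confusion aggregate. The reported feature weights
    come from a final fit on all samples (standardized scale).
    """
    labels, positive = _check_inputs(features, labels, positive)
    if len(features) < 4:
        raise ConfigError("LOOCV needs at least four samples")
    y = (labels == positive).astype(int)
    negative = [c for c in sorted(set(labels)) if c != positive][0]
    fold_seeds = _seed_ints(seed, len(features) + 1)

    def make_model(rs: int, n_splits: int) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "lasso",
                    LogisticRegressionCV(
                        Cs=Cs,
                        cv=StratifiedKFold(n_splits, shuffle=True, random_state=rs),
                        penalty="l1",
                        solver="liblinear",
                        scoring="accuracy",
                        max_iter=2000,
                        random_state=rs,
                    ),
                ),
            ]
        )

    def fit_quiet(model, X, y_arr):
        # sklearn 1.9 warns about the upcoming penalty -> l1_ratios API change
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(X, y_arr)

    rows = []
    flagged = []
    for i, sample in enumerate(features.index):
        train_idx = features.index != sample
        y_train = y[train_idx]
        if y_train.nunique() < 2:
            flagged.append(sample)
            continue
        splits = max(2, min(inner_cv, int(y_train.value_counts().min())))
        model = make_model(fold_seeds[i], splits)
        fit_quiet(model, features.loc[train_idx].to_numpy(), y_train.to_numpy())
        lr = model.named_steps["lasso"]
        if not np.any(lr.coef_) and abs(float(lr.intercept_[0])) < 1e-9:
            # penalty collapsed the model entirely (liblinear also shrinks
            # the intercept): fall back to the training-majority prediction
            prob = float(y_train.mean())
        else:
            prob = float(model.predict_proba(features.loc[[sample]].to_numpy())[0, 1])
        pred = positive if prob >= 0.5 else negative
        rows.append(
            {"sample_id": sample, "true": labels[sample], "predicted": pred, "prob": prob}
        )
    predictions = pd.DataFrame(rows)
    tp, fn, tn, fp = confusion_counts(predictions["true"], predictions["predicted"], positive)
    sens, spec = sensitivity_specificity(tp, fn, tn, fp)

    final = make_model(fold_seeds[-1], max(2, min(inner_cv, int(y.value_counts().min()))))
    fit_quiet(final, features.to_numpy(), y.to_numpy())
    weights = pd.Series(
        final.named_steps["lasso"].coef_.ravel(), index=features.columns, name="coef"
    )
    return ClassifierReport(
        kind="lasso_loocv",
        positive=positive,
        predictions=predictions,
        sensitivity=sens,
        specificity=spec,
        feature_weights=weights,
        flagged=flagged,
    )


def rf_ensemble(
    features: pd.DataFrame,
    labels: pd.Series,
    n_models: int = 100,
    n_trees: int = 200,
    seed: int = 0,
    positive: str = POSITIVE_GROUP,
) -> ClassifierReport:
    """Out-of-bag-evaluated random-forest ensemble.

    Per model: a forest of ``n_trees`` bootstrap trees with sqrt(p)
    features per split; every sample is predicted by majority vote of its
    OOB trees (probability ties go to the positive class) and the model's
    sensitivity/specificity follow from that confusion matrix. Reported
    metrics are means over models with mean +/- 1.96 sd/sqrt(n_models)
    CIs. Proximities and Gini importances are averaged over models.
    """
    labels, positive = _check_inputs(features, labels, positive)
    y = (labels == positive).astype(int).to_numpy()
    X = features.to_numpy()
    n = len(features)
    negative = [c for c in sorted(set(labels)) if c != positive][0]
    model_seeds = _seed_ints(seed, n_models)

    per_model = []
    vote_pos = np.zeros(n)
    vote_n = np.zeros(n)
    prox_sum = np.zeros((n, n))
    imp_sum = np.zeros(features.shape[1])
    flagged = []
    for m, rs in enumerate(model_seeds):
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=rs,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
            forest.fit(X, y)
        oob = forest.oob_decision_function_  # n x 2, class order [0, 1]
        valid = ~np.isnan(oob).any(axis=1) & (oob.sum(axis=1) > 0)
        if not valid.all():
            flagged.append({"model": m, "samples_without_oob": list(features.index[~valid])})
        p_pos = oob[valid, list(forest.classes_).index(1)]
        pred = (p_pos >= 0.5).astype(int)  # tie -> positive class
        tp, fn, tn, fp = confusion_counts(y[valid], pred, positive=1)
        sens, spec = sensitivity_specificity(tp, fn, tn, fp)
        per_model.append({"model": m, "seed": rs, "sensitivity": sens, "specificity": spec})
        vote_pos[valid] += pred
        vote_n[valid] += 1

        leaves = forest.apply(X)  # n x n_trees terminal-node ids
        prox_sum += (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
        imp_sum += forest.feature_importances_

    per_model = pd.DataFrame(per_model)
    means = per_model[["sensitivity", "specificity"]].mean()
    sds = per_model[["sensitivity", "specificity"]].std(ddof=1)
    half = Z95 * sds / np.sqrt(n_models) if n_models > 1 else sds * 0.0

    def ci(metric):
        lo = max(0.0, means[metric] - half[metric])
        hi = min(1.0, means[metric] + half[metric])
        return (float(lo), float(hi))

    frac_pos = np.divide(vote_pos, vote_n, out=np.full(n, np.nan), where=vote_n > 0)
    predictions = pd.DataFrame(
        {
            "sample_id": features.index,
            "true": labels.to_numpy(),
            "oob_vote_positive": frac_pos,
            "predicted": np.where(frac_pos >= 0.5, positive, negative),
        }
    )
    proximity = pd.DataFrame(
        prox_sum / n_models, index=features.index, columns=features.index
    )
    np.fill_diagonal(proximity.values, 1.0)
    importances = pd.Series(
        imp_sum / n_models, index=features.columns, name="mean_decrease_gini"
    )
    return ClassifierReport(
        kind="rf_ensemble",
        positive=positive,
        predictions=predictions,
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        sensitivity_ci=ci("sensitivity"),
        specificity_ci=ci("specificity"),
        per_model=per_model,
        importances=importances,
        proximity=proximity,
        flagged=flagged,
    )


def proximity_impute(
    features: pd.DataFrame,
    labels: pd.Series,
    n_iter: int = 5,
    seed: int = 0,
    n_trees: int = 200,
) -> pd.DataFrame:
    """Forest-proximity imputation of missing feature values.

    Missing cells start at their feature mean; each round fits a forest on
    the current complete matrix and replaces every missing cell with the
    proximity-weighted average of that feature's observed values. Imputed
    values are convex combinations of observations, hence always within
    the observed range. Deterministic under a fixed seed.
    """
    if not features.isna().any().any():
        return features.copy()
    if (features.notna().sum(axis=0) == 0).any():
        raise ConfigError("every feature needs at least one observed value")
    labels = labels.loc[features.index]
    y = pd.factorize(labels)[0]
    missing = features.isna()
    current = features.fillna(features.mean(axis=0, skipna=True))
    iter_seeds = _seed_ints(seed, n_iter)
    for rs in iter_seeds:
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=rs
        )
        forest.fit(current.to_numpy(), y)
        leaves = forest.apply(current.to_numpy())
        prox = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
        np.fill_diagonal(prox, 0.0)  # a sample cannot donate its own missing value
        new = current.copy()
        for j, col in enumerate(features.columns):
            miss_rows = np.flatnonzero(missing[col].to_numpy())
            if miss_rows.size == 0:
                continue
            obs_rows = np.flatnonzero(~missing[col].to_numpy())
            obs_vals = features[col].to_numpy()[obs_rows]
            for i in miss_rows:
                w = prox[i, obs_rows]
                total = w.sum()
                if total > 0:
                    new.iloc[i, j] = float(np.dot(w, obs_vals) / total)
        current = new
    return current
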