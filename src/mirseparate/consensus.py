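"""Consensus feature selection across the four analysis methods.

Each method nominates its most discriminatory miRNAs — smallest t-test
p-values, largest |PC1 loading|, largest mean decrease in Gini, and the
features the L1 penalty retains — and the overlap structure across those
lists (pairwise intersections and the ">= 2 methods" tier) identifies the
markers the analyses agree on.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .classifiers import ClassifierReport
from .exceptions import ConfigError
from .multivariate import PcaModel, loading_rank
from .univariate import UnivariateResult

METHODS = ("t_test", "pca", "lasso", "rf")


@dataclass
class ConsensusSelection:
    """Per-method selections and every overlap derived from them."""

    lists: dict  # method -> ordered feature list
    pairwise: dict  # frozenset({m1, m2}) -> sorted intersection
    multi_method: list  # features selected by >= 2 methods
    adjacency: pd.DataFrame  # methods x methods pairwise intersection sizes

    def methods_of(self, feature: str) -> list[str]:
        return [m for m in self.lists if feature in self.lists[m]]


def overlap_sets(lists: dict[str, list[str]]) -> ConsensusSelection:
    """Overlap structure of per-method feature lists (pure set arithmetic)."""
    methods = list(lists)
    pairwise = {
        frozenset((a, b)): sorted(set(lists[a]) & set(lists[b]))
        for a, b in combinations(methods, 2)
    }
    counts: dict[str, int] = {}
    for feats in lists.values():
        for f in set(feats):
            counts[f] = counts.get(f, 0) + 1
    multi = sorted(f for f, c in counts.items() if c >= 2)
    adjacency = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    for m in methods:
        adjacency.loc[m, m] = len(set(lists[m]))
    for (a, b), inter in pairwise.items():
        a, b = sorted((a, b))
        adjacency.loc[a, b] = adjacency.loc[b, a] = len(inter)
    return ConsensusSelection(
        lists=dict(lists), pairwise=pairwise, multi_method=multi, adjacency=adjacency
    )


def select_consensus(
    univ: UnivariateResult,
    pca: PcaModel,
    rf: ClassifierReport,
    lasso: ClassifierReport,
    k: int = 5,
) -> ConsensusSelection:
    """Top-k per ranked method plus all LASSO-retained features.

    All four inputs must have been computed on the same feature universe;
    a mismatch raises with the differing features listed. Rankings break
    ties by feature id, so the selection is a pure function of its inputs.
    """
    universes = {
        "t_test": set(univ.table["assay_id"]),
        "pca": set(pca.loadings.index),
        "rf": set(rf.importances.index) if rf.importances is not None else set(),
        "lasso": set(lasso.feature_weights.index) if lasso.feature_weights is not None else set(),
    }
    reference = universes["t_test"]
    for method, uni in universes.items():
        if uni != reference:
            diff = sorted(reference ^ uni)
            raise ConfigError(f"feature universe mismatch for {method}: {diff}")
    lists = {
        "t_test": univ.top_k(k),
        "pca": loading_rank(pca, component=1, k=k),
        "lasso": lasso.retained_features,
        "rf": rf.top_importance(k),
    }
    return overlap_sets(lists)
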