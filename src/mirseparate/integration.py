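"""Cross-biofluid feature integration.

Every pairing of a CSF-detectable miRNA's CSF Ct with a CSF-panel miRNA's
plasma Ct is tested for Pearson correlation over the samples measured in
both fluids (pairwise-complete). Pairs passing a two-tailed p < alpha gate
become new multiplied features, ``Ct_CSF x Ct_plasma`` (squared-Ct units),
which downstream heatmaps, t-tests, PCA and classifiers consume like any
other feature block. No multiplicity correction is applied at the gate —
it is a feature-construction heuristic, not an inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CtMatrix


@dataclass
class CorrelationGate:
    """All tested (CSF miRNA, plasma miRNA) pairs with r, p and the gate flag."""

    pairs: pd.DataFrame  # csf_assay, plasma_assay, n, r, p, selected, skipped
    alpha: float

    @property
    def selected(self) -> pd.DataFrame:
        return self.pairs[self.pairs["selected"]]

    @property
    def n_selected(self) -> int:
        return int(self.pairs["selected"].sum())


def cross_fluid_correlation(
    csf: CtMatrix, plasma: CtMatrix, alpha: float = 0.05
) -> CorrelationGate:
    """Pearson-correlate every CSF-panel miRNA against the same panel in plasma.

    The pair universe is the full CSF panel x (CSF panel as measured in
    plasma) grid — the reading under which the 11-marker CSF panel yields
    an 11 x 11 correlation matrix. Pairs with fewer than three complete
    shared samples are skipped with a flag. p-values come from the exact
    t-transform t = r * sqrt((n-2) / (1-r^2)), two-sided.
    """
    shared = [s for s in csf.sample_ids if s in set(plasma.sample_ids)]
    csf_assays = csf.assay_ids
    plasma_assays = [a for a in csf_assays if a in set(plasma.assay_ids)]
    rows = []
    for ca in csf_assays:
        x_all = csf.values.loc[shared, ca]
        for pa in plasma_assays:
            y_all = plasma.values.loc[shared, pa]
            ok = x_all.notna() & y_all.notna()
            n = int(ok.sum())
            if n < 3:
                rows.append(
                    {
                        "csf_assay": ca,
                        "plasma_assay": pa,
                        "n": n,
                        "r": np.nan,
                        "p": np.nan,
                        "selected": False,
                        "skipped": True,
                    }
                )
                continue
            x = x_all[ok].to_numpy()
            y = y_all[ok].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "csf_assay": ca,
                    "plasma_assay": pa,
                    "n": n,
                    "r": float(r),
                    "p": float(p),
                    "selected": bool(p < alpha) if not np.isnan(p) else False,
                    "skipped": False,
                }
            )
    return CorrelationGate(pairs=pd.DataFrame(rows), alpha=alpha)


@dataclass
class MultipliedMatrix:
    """Samples x selected-pairs matrix of Ct_CSF x Ct_plasma products."""

    values: pd.DataFrame

    @property
    def is_empty(self) -> bool:
        return self.values.shape[1] == 0


def pair_id(csf_assay: str, plasma_assay: str) -> str:
    return f"{csf_assay}(CSF)x{plasma_assay}(plasma)"


def build_multiplied_features(
    gate: CorrelationGate, csf: CtMatrix, plasma: CtMatrix
) -> MultipliedMatrix:
    """One multiplied feature per gate-selected pair, on raw calibrated Cts.

    The product is missing wherever either factor is missing; imputation
    is left to each downstream consumer. Only samples measured in both
    fluids appear. With no selected pairs an empty matrix is returned and
    downstream stages skip.
    """
    shared = [s for s in csf.sample_ids if s in set(plasma.sample_ids)]
    cols = {}
    for _, row in gate.selected.iterrows():
        name = pair_id(row["csf_assay"], row["plasma_assay"])
        cols[name] = (
            csf.values.loc[shared, row["csf_assay"]]
            * plasma.values.loc[shared, row["plasma_assay"]]
        )
    values = pd.DataFrame(cols, index=shared)
    return MultipliedMatrix(values=values)
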