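"""Global-mean delta-delta-Ct fold changes and row z-scoring.

The endogenous reference is the per-individual global mean: for each sample
``mean_ct`` is the average Ct over that sample's detected miRNAs, and
``dCt = Ct - mean_ct``. The healthy-control group serves as the reference
group: ``ddCt = dCt - mean(dCt over HC)`` per miRNA, fold change
``fc = 2**(-ddCt)`` and ``log2fc = -ddCt`` (computed analytically, not by
logging the fold change). The HC group therefore has mean log2fc zero —
equivalently, geometric-mean fold change one — for every miRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CohortTable, CtMatrix
from .exceptions import NoReferenceError


@dataclass
class FoldChangeTable:
    """Per (sample, miRNA) ddCt quantities plus the intermediates.

    ``table`` columns: sample_id, assay_id, delta_ct, delta_delta_ct, fc,
    log2fc. ``mean_ct`` is the per-sample global mean over detected
    miRNAs; ``reference_mean_dct`` the per-miRNA mean dCt over the
    reference group.
    """

    table: pd.DataFrame
    mean_ct: pd.Series
    reference_mean_dct: pd.Series
    reference_group: str
    fluid: str

    def wide(self, column: str = "log2fc") -> pd.DataFrame:
        """Samples x miRNAs matrix of one derived quantity."""
        return self.table.pivot(index="sample_id", columns="assay_id", values=column)


def compute_fold_changes(
    matrix: CtMatrix,
    cohort: CohortTable,
    reference_group: str = "HC",
) -> FoldChangeTable:
    """Fold changes relative to the reference group's mean dCt profile.

    Missing Ct values propagate to missing outputs; a miRNA with no
    detected value in any reference-group sample cannot be referenced and
    raises :class:`NoReferenceError`.
    """
    values = matrix.values
    mean_ct = values.mean(axis=1, skipna=True)
    delta_ct = values.sub(mean_ct, axis=0)

    ref_samples = [s for s in cohort.samples_in(reference_group) if s in values.index]
    if not ref_samples:
        raise NoReferenceError(f"no {reference_group} samples in the matrix")
    ref_dct = delta_ct.loc[ref_samples]
    empty = ref_dct.columns[ref_dct.notna().sum(axis=0) == 0]
    if len(empty) > 0:
        raise NoReferenceError(
            f"no detected {reference_group} value for: {', '.join(empty)}"
        )
    reference_mean_dct = ref_dct.mean(axis=0, skipna=True)

    ddct = delta_ct.sub(reference_mean_dct, axis=1)
    long = pd.DataFrame(
        {
            "delta_ct": delta_ct.stack(future_stack=True),
            "delta_delta_ct": ddct.stack(future_stack=True),
        }
    ).reset_index()
    long.columns = ["sample_id", "assay_id", "delta_ct", "delta_delta_ct"]
    long["fc"] = np.exp2(-long["delta_delta_ct"])
    long["log2fc"] = -long["delta_delta_ct"]
    long = long[["sample_id", "assay_id", "delta_ct", "delta_delta_ct", "fc", "log2fc"]]
    return FoldChangeTable(
        table=long,
        mean_ct=mean_ct,
        reference_mean_dct=reference_mean_dct,
        reference_group=reference_group,
        fluid=matrix.fluid,
    )


def row_zscores(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row over its non-missing entries (sample-sd, ddof=1).

    Missing entries stay missing. A constant row has no defined scale and
    is emitted as zeros with a warning.
    """
    out = frame.copy().astype(float)
    for idx in out.index:
        row = out.loc[idx]
        present = row.dropna()
        if len(present) < 2 or present.std(ddof=1) == 0:
            warnings.warn(f"row {idx!r} is constant; z-scores set to 0", stacklevel=2)
            out.loc[idx] = row.where(row.isna(), 0.0)
            continue
        out.loc[idx] = (row - present.mean()) / present.std(ddof=1)
    return out
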