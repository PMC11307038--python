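"""Core in-memory containers shared across pipeline stages.

The pipeline works on three biological groups — LRRK2 mutation carriers
(``LRRK2_MC``), sporadic Parkinson's disease patients (``sPD``) and healthy
controls (``HC``) — measured in two biofluids (``plasma``, ``CSF``). Cycle
threshold (Ct) values live on a log2 abundance scale: one cycle difference
corresponds to a two-fold difference in template amount, and *lower* Ct
means *higher* abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUPS = ("LRRK2_MC", "sPD", "HC")
FLUIDS = ("plasma", "CSF")

#: Positive class for every sensitivity / specificity readout.
POSITIVE_GROUP = "LRRK2_MC"

#: Spike-in assay classes, plus the no-primer negative control.
SPIKE_CLASSES = ("unispike2", "unispike3", "unispike4", "unispike6")
ASSAY_CLASSES = ("target",) + SPIKE_CLASSES + ("blank",)


@dataclass
class RawPlate:
    """One qPCR plate: target wells plus spike-in controls and a blank.

    ``wells`` columns: well, sample_id, assay_id, assay_class, fluid, ct.
    Undetected reactions are NaN in ``ct``. Every plate carries at least one
    UniSpike 3 well; those anchor the interplate calibration. A plate can
    host panel blocks from both biofluids, so fluid is a well property.
    """

    plate_id: str
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.wells["fluid"]) - set(FLUIDS)
        if bad:
            raise ValueError(f"unknown fluids {sorted(bad)}")
        dup = self.wells.loc[
            self.wells["assay_class"] == "target", ["sample_id", "assay_id", "fluid"]
        ].duplicated()
        if dup.any():
            from .exceptions import DuplicateWellError

            raise DuplicateWellError(
                f"plate {self.plate_id}: duplicate (sample, assay) target wells"
            )

    def spike_wells(self, spike_class: str) -> pd.DataFrame:
        return self.wells[self.wells["assay_class"] == spike_class]

    @property
    def target_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["assay_class"] == "target"]


@dataclass
class CtMatrix:
    """Samples x assays matrix of (calibrated) Ct values for one biofluid.

    Missingness is encoded as NaN; ``mask`` exposes it explicitly.
    """

    values: pd.DataFrame
    fluid: str

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValueError(f"unknown fluid {self.fluid!r}")

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is present."""
        return self.values.notna()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "CtMatrix":
        keep = [s for s in self.values.index if s in set(sample_ids)]
        return CtMatrix(self.values.loc[keep].copy(), self.fluid)

    def drop_samples(self, sample_ids) -> "CtMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.values.index if s not in drop]
        return CtMatrix(self.values.loc[keep].copy(), self.fluid)


@dataclass
class CohortTable:
    """Per-sample metadata: group label, symptomatic flag, fluid availability."""

    table: pd.DataFrame  # index sample_id; columns group, symptomatic, has_plasma, has_csf

    def __post_init__(self) -> None:
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in cohort")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups_of(self, sample_ids) -> pd.Series:
        return self.table.loc[list(sample_ids), "group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_sizes(self) -> pd.Series:
        return self.table["group"].value_counts()


@dataclass
class QcReport:
    """Report-only quality control bookkeeping.

    ``spike_checks``: per (plate, spike) mean Ct and pass flag.
    ``blank_violations``: detected blank wells (should be none).
    ``missing_by_group``: per-feature missing counts by group with the
    exact balance-test p-value ("did missingness hit all groups equally?").
    """

    spike_checks: pd.DataFrame = field(default_factory=pd.DataFrame)
    blank_violations: pd.DataFrame = field(default_factory=pd.DataFrame)
    missing_by_group: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_features: list[str] = field(default_factory=list)
    n_censored: int = 0
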