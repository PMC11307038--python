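"""Interplate spike-in calibration, censoring and feature-retention filters.

UniSpike 3 wells are shared across plates at a fixed nominal amount, so any
systematic difference between a plate's UniSpike 3 mean and the pooled
UniSpike 3 mean measures that plate's Ct offset. Subtracting this per-plate
calibration factor from every Ct on the plate removes interplate variation;
by construction the procedure is invariant to arbitrary per-plate shifts
and idempotent (recalibrating yields factors of zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .datatypes import CohortTable, CtMatrix, QcReport, RawPlate, SPIKE_CLASSES
from .exceptions import CalibrationError, EmptyPanelError

CALIBRATION_SPIKE = "unispike3"


@dataclass
class CalibrationFactors:
    """Per-plate offsets: plate's UniSpike 3 mean minus the pooled mean."""

    factors: pd.Series  # index plate_id, Ct units
    grand_mean: float  # pooled mean of all detected UniSpike 3 Cts

    def __getitem__(self, plate_id: str) -> float:
        return float(self.factors[plate_id])


def compute_calibration_factors(plates: list[RawPlate]) -> CalibrationFactors:
    all_cts: list[np.ndarray] = []
    plate_means: dict[str, float] = {}
    for plate in plates:
        cts = plate.spike_wells(CALIBRATION_SPIKE)["ct"].dropna().to_numpy()
        if cts.size == 0:
            raise CalibrationError(
                f"plate {plate.plate_id} has no detected {CALIBRATION_SPIKE} well"
            )
        plate_means[plate.plate_id] = float(cts.mean())
        all_cts.append(cts)
    grand_mean = float(np.concatenate(all_cts).mean())
    factors = pd.Series(plate_means, name="calibration_factor") - grand_mean
    return CalibrationFactors(factors=factors, grand_mean=grand_mean)


def apply_calibration(
    plates: list[RawPlate], factors: CalibrationFactors
) -> dict[str, CtMatrix]:
    """Calibrated Ct = raw Ct - CF(plate), target wells only, one matrix per fluid."""
    frames = []
    for plate in plates:
        if plate.plate_id not in factors.factors.index:
            raise CalibrationError(f"no calibration factor for plate {plate.plate_id}")
        targets = plate.target_wells.copy()
        targets["ct"] = targets["ct"] - factors[plate.plate_id]
        frames.append(targets)
    wells = pd.concat(frames, ignore_index=True)
    matrices = {}
    for fluid, grp in wells.groupby("fluid"):
        wide = grp.pivot_table(
            index="sample_id", columns="assay_id", values="ct", aggfunc="mean", dropna=False
        )
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        wide.index.name = None
        wide.columns.name = None
        matrices[str(fluid)] = CtMatrix(wide, str(fluid))
    return matrices


def exact_missingness_balance(n_missing: pd.Series, group_sizes: pd.Series) -> float:
    """Exact probability that missingness is this unevenly split across groups.

    Conditional on the total number of missing samples, under the null of
    group-independent missingness the per-group missing counts follow a
    multivariate hypergeometric law. The p-value sums the probability of
    every split at most as likely as the observed one (the exact analogue
    of Fisher's test for a groups x {missing, present} table; identical to
    Fisher's exact test when there are two groups).
    """
    groups = list(group_sizes.index)
    n = [int(group_sizes[g]) for g in groups]
    m_obs = [int(n_missing.get(g, 0)) for g in groups]
    k = sum(m_obs)
    if k == 0:
        return 1.0
    total = comb(sum(n), k)

    def prob(split):
        return np.prod([comb(ng, mg) for ng, mg in zip(n, split)]) / total

    p_obs = prob(m_obs)
    p_val = 0.0
    splits: list[list[int]] = [[]]
    for i, ng in enumerate(n):
        remaining = n[i + 1 :]
        cap_rest = sum(remaining)
        new = []
        for s in splits:
            used = sum(s)
            lo = max(0, k - used - cap_rest)
            hi = min(ng, k - used)
            for m in range(lo, hi + 1):
                new.append(s + [m])
        splits = new
    for s in splits:
        p = prob(s)
        if p <= p_obs * (1 + 1e-12):
            p_val += p
    return float(min(p_val, 1.0))


def censor_and_filter(
    matrix: CtMatrix,
    cohort: CohortTable,
    censor_ct: float = 40.0,
    max_missing_individuals: int = 1,
    alpha: float = 0.05,
) -> tuple[CtMatrix, QcReport]:
    """Apply the detection-limit censoring and feature-retention rules.

    Ct values strictly above ``censor_ct`` become missing (a value of
    exactly ``censor_ct`` is retained); features missing in strictly more
    than ``max_missing_individuals`` samples are dropped. The QC report
    tabulates, per feature, missing counts by group with an exact balance
    test — report-only, mirroring how unbalanced dropout would be inspected
    rather than auto-excluded.
    """
    values = matrix.values.copy()
    n_censored = int((values > censor_ct).sum().sum())
    values = values.where(values <= censor_ct)

    groups = cohort.groups_of(values.index)
    group_sizes = groups.value_counts()
    missing = values.isna()
    rows = []
    for assay in values.columns:
        by_group = missing[assay].groupby(groups).sum()
        total = int(missing[assay].sum())
        rows.append(
            {
                "assay_id": assay,
                "n_missing": total,
                **{f"missing_{g}": int(by_group.get(g, 0)) for g in group_sizes.index},
                "balance_p": exact_missingness_balance(by_group, group_sizes),
                "retained": total <= max_missing_individuals,
            }
        )
    report_table = pd.DataFrame(rows)
    report_table["balance_flag"] = report_table["balance_p"] < alpha

    keep = report_table.loc[report_table["retained"], "assay_id"].tolist()
    if not keep:
        raise EmptyPanelError(
            f"no {matrix.fluid} feature survives the missing<= {max_missing_individuals} rule"
        )
    dropped = [a for a in values.columns if a not in set(keep)]
    filtered = CtMatrix(values[keep].copy(), matrix.fluid)
    report = QcReport(
        missing_by_group=report_table,
        dropped_features=dropped,
        n_censored=n_censored,
    )
    return filtered, report


def spike_in_qc(
    plates: list[RawPlate],
    thresholds: dict[str, tuple[float, float]] | None = None,
    censor_ct: float = 40.0,
) -> QcReport:
    """Report-only spike-in and blank-well checks.

    ``thresholds`` maps spike class to an acceptable (low, high) Ct window;
    a plate passes a spike if every detected well of that spike falls in
    the window and at least one well is detected. Blank wells must be
    undetected (or beyond the censoring limit); any detected blank is a
    primer-contamination flag for its plate.
    """
    thresholds = thresholds or {}
    checks = []
    blanks = []
    for plate in plates:
        for spike in SPIKE_CLASSES:
            wells = plate.spike_wells(spike)
            if wells.empty:
                continue
            detected = wells["ct"].dropna()
            mean_ct = float(detected.mean()) if not detected.empty else np.nan
            ok = not detected.empty
            if spike in thresholds and ok:
                lo, hi = thresholds[spike]
                ok = bool(((detected >= lo) & (detected <= hi)).all())
            checks.append(
                {
                    "plate_id": plate.plate_id,
                    "spike": spike,
                    "n_wells": len(wells),
                    "n_detected": int(detected.size),
                    "mean_ct": mean_ct,
                    "passed": ok,
                }
            )
        blank = plate.wells[plate.wells["assay_class"] == "blank"]
        bad = blank[blank["ct"].notna() & (blank["ct"] <= censor_ct)]
        for _, row in bad.iterrows():
            blanks.append(
                {
                    "plate_id": plate.plate_id,
                    "well": row["well"],
                    "sample_id": row["sample_id"],
                    "ct": float(row["ct"]),
                }
            )
    return QcReport(
        spike_checks=pd.DataFrame(checks),
        blank_violations=pd.DataFrame(blanks, columns=["plate_id", "well", "sample_id", "ct"]),
    )
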