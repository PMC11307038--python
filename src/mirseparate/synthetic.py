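"""Synthetic-cohort generator for raw qPCR plate data.

Emulates the data structure the downstream pipeline assumes: a three-group
cohort (LRRK2 mutation carriers, sporadic PD, healthy controls) measured on
custom ~91-assay miRNA panels in plasma and CSF, with per-plate Ct offsets,
UniSpike 2/3/4/6 spike-in controls, a blank (no-primer) negative-control
well, and right-censoring of reactions beyond the Ct detection limit.

The noise model is additive Gaussian on the Ct scale at three levels —
assay (abundance spread across the panel), plate (interplate shift, later
removed by spike-in calibration) and well (technical plus biological
variation). Group differences are planted as per-assay Ct shifts; because
Ct is a log2 scale, a shift of delta cycles corresponds (after the
global-mean delta-delta-Ct normalization) to a log2 fold change of
``-delta`` up to a small panel-mean renormalization that the returned
:class:`GroundTruth` accounts for exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EffectEntry, SimConfig, NAMED_ASSAYS
from .datatypes import GROUPS, CohortTable, RawPlate
from .exceptions import ConfigError

#: Group-mean log2 fold changes (vs healthy controls, plasma) that the
#: default cohort is calibrated to reproduce in expectation for the five
#: discriminatory miRNAs; all other assays are null.
DEFAULT_LOG2FC_TARGETS: dict[str, dict[str, float]] = {
    "miR-29c-3p": {"LRRK2_MC": -0.39, "sPD": 0.62},
    "miR-425-5p": {"LRRK2_MC": -0.33, "sPD": 0.54},
    "miR-153-3p": {"LRRK2_MC": -0.97, "sPD": 0.65},
    "miR-148a-3p": {"LRRK2_MC": -0.60, "sPD": 0.38},
    "miR-128-3p": {"LRRK2_MC": -1.01, "sPD": 0.03},
}


@dataclass
class GroundTruth:
    """What the generator planted, and what the pipeline should recover.

    ``effects`` has one row per (assay, group, fluid) — zero-shift assays
    included — with the planted Ct shift and the exact expected log2 fold
    change versus the reference group under the noise-free model (i.e.
    including the global-mean renormalization of the ddCt method).
    Expectations assume the full panel survives filtering; if censoring
    drops assays, the global-mean term is renormalized over the retained
    panel and the expectation shifts by the (small) difference in the
    group's mean planted shift.
    """

    effects: pd.DataFrame
    n_censored: dict
    plate_layout: pd.DataFrame
    reference_group: str = "HC"

    def expected_log2fc(self, assay: str, group: str, fluid: str = "plasma") -> float:
        e = self.effects
        row = e[(e["assay"] == assay) & (e["group"] == group) & (e["fluid"] == fluid)]
        if row.empty:
            raise KeyError((assay, group, fluid))
        return float(row["expected_log2fc"].iloc[0])


def effects_for_log2fc_targets(
    targets: dict[str, dict[str, float]],
    panel: list[str],
    fluid: str | None = "plasma",
) -> tuple[EffectEntry, ...]:
    """Planted Ct shifts whose expected group-mean log2fc equals ``targets``.

    The global-mean ddCt normalization maps shifts ``delta_a`` of group g to
    expected log2fc ``-(delta_a - mean_panel(delta_g))`` (healthy reference
    unshifted), so matching printed log2fc means requires solving for the
    group's panel-mean shift: with T targeted assays of m on the panel and
    target sum S, ``mean_panel(delta_g) = -S / (m - T)`` and
    ``delta_a = mean_panel(delta_g) - target_a``.
    """
    m = len(panel)
    missing = set(targets) - set(panel)
    if missing:
        raise ConfigError(f"target assays not on the panel: {sorted(missing)}")
    by_group: dict[str, dict[str, float]] = {}
    for assay, per_group in targets.items():
        for group, val in per_group.items():
            by_group.setdefault(group, {})[assay] = val
    entries = []
    for group, assay_targets in by_group.items():
        T = len(assay_targets)
        if T >= m:
            raise ConfigError("cannot target every assay on the panel")
        mean_shift = -sum(assay_targets.values()) / (m - T)
        for assay, target in assay_targets.items():
            entries.append(EffectEntry(assay, group, mean_shift - target, fluid))
    return tuple(entries)


def default_sim_config(seed: int = 0) -> SimConfig:
    """The study-condition cohort: 10/10/11 samples, 91-plex dual-fluid panels.

    The five discriminatory miRNAs carry plasma group shifts calibrated to
    the target log2fc means; eleven named assays are exempt from the CSF
    abundance penalty (modelling the abundant subset that stays detectable
    in CSF) and share well noise across fluids so their plasma and CSF Ct
    values correlate.
    """
    panel = SimConfig().panel("plasma")
    csf_panel = tuple(NAMED_ASSAYS[:11])
    return SimConfig(
        effect_table=effects_for_log2fc_targets(DEFAULT_LOG2FC_TARGETS, panel),
        csf_shift=12.0,
        csf_detectable_assays=csf_panel,
        correlated_assays=csf_panel,
        cross_fluid_rho=0.5,
        seed=seed,
    )


def generate_cohort(config: SimConfig) -> CohortTable:
    """Sample ids, group labels, symptomatic flags and fluid availability."""
    rows = []
    for group, n in (("LRRK2_MC", config.n_lrrk2), ("sPD", config.n_spd), ("HC", config.n_hc)):
        n_asym = round(config.asymptomatic_fraction * n) if group == "LRRK2_MC" else 0
        for i in range(n):
            symptomatic = {"LRRK2_MC": i < n - n_asym, "sPD": True, "HC": False}[group]
            rows.append(
                {
                    "sample_id": f"{group}-{i + 1:02d}",
                    "group": group,
                    "symptomatic": symptomatic,
                    "has_plasma": True,
                    "has_csf": True,
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    return CohortTable(table)


def _shift_lookup(config: SimConfig, fluid: str) -> dict[tuple[str, str], float]:
    """(assay, group) -> planted Ct shift for one fluid (fluid-None applies to both)."""
    shifts: dict[tuple[str, str], float] = {}
    for e in config.effect_table:
        if e.fluid is None or e.fluid == fluid:
            shifts[(e.assay, e.group)] = shifts.get((e.assay, e.group), 0.0) + e.shift_ct
    return shifts


def _expected_effects(config: SimConfig) -> pd.DataFrame:
    """Exact expected log2fc vs HC for every (assay, group, fluid) under zero noise."""
    rows = []
    for fluid in ("plasma", "CSF"):
        panel = config.panel(fluid)
        shifts = _shift_lookup(config, fluid)
        mean_shift = {
            g: np.mean([shifts.get((a, g), 0.0) for a in panel]) for g in GROUPS
        }
        for group in GROUPS:
            for assay in panel:
                d = shifts.get((assay, group), 0.0)
                d_ref = shifts.get((assay, "HC"), 0.0)
                expected = -((d - mean_shift[group]) - (d_ref - mean_shift["HC"]))
                rows.append(
                    {
                        "assay": assay,
                        "group": group,
                        "fluid": fluid,
                        "planted_shift_ct": d,
                        "expected_log2fc": expected,
                    }
                )
    return pd.DataFrame(rows)


def simulate_raw_plates(
    cohort: CohortTable, config: SimConfig
) -> tuple[list[RawPlate], GroundTruth]:
    """Simulate raw plates for every sample and fluid.

    Each sample's panel occupies a contiguous block of wells on a single
    plate (panels never span plates); sample-fluid panels are dealt to the
    ``n_plates`` plates round-robin. Every panel block carries the full
    target panel plus one well each of UniSpike 2/3/4/6 (at their nominal
    Ct plus that plate's offset and well noise) and one blank well, which
    is always undetected. Target wells whose simulated Ct exceeds
    ``censor_ct`` are recorded as undetected (NaN).
    """
    rng = np.random.default_rng(config.seed)
    union_panel = config.panel("plasma")
    if config.n_assays_csf > config.n_assays_plasma:
        union_panel = config.panel("CSF")
    assay_offset = dict(zip(union_panel, rng.normal(0.0, config.baseline_ct_sd, len(union_panel))))
    # The last fraction of the panel models low-abundance miRNAs riding the
    # detection limit; the shift is assay-level, so it cancels in ddCt and
    # only shapes the dropout pattern.
    n_low = int(round(config.low_abundance_fraction * len(union_panel)))
    for assay in union_panel[len(union_panel) - n_low :]:
        assay_offset[assay] += config.low_abundance_shift
    plate_ids = [f"P{i + 1:02d}" for i in range(config.n_plates)]
    plate_offset = dict(zip(plate_ids, rng.normal(0.0, config.plate_offset_sd, config.n_plates)))

    samples = cohort.sample_ids
    if config.outlier_sample is not None and config.outlier_sample[0] not in samples:
        raise ConfigError(f"outlier sample {config.outlier_sample[0]!r} not in cohort")

    # Deal (sample, fluid) panel blocks to plates round-robin.
    blocks = [(s, f) for s in samples for f in ("plasma", "CSF")]
    layout = {
        (s, f): plate_ids[i % config.n_plates] for i, (s, f) in enumerate(blocks)
    }

    shifts = {f: _shift_lookup(config, f) for f in ("plasma", "CSF")}
    corr = set(config.correlated_assays)
    csf_ok = set(config.csf_detectable_assays)
    rho = config.cross_fluid_rho

    plate_wells: dict[str, list] = {p: [] for p in plate_ids}
    counters = {p: 0 for p in plate_ids}
    n_censored = {"plasma": 0, "CSF": 0}

    def add_well(plate, sample, assay, aclass, fluid, ct):
        counters[plate] += 1
        plate_wells[plate].append(
            {
                "well": f"w{counters[plate]:04d}",
                "sample_id": sample,
                "assay_id": assay,
                "assay_class": aclass,
                "fluid": fluid,
                "ct": ct,
            }
        )

    panels = {f: config.panel(f) for f in ("plasma", "CSF")}
    for sample in samples:
        group = cohort.table.loc[sample, "group"]
        outlier_shift = 0.0
        if config.outlier_sample is not None and sample == config.outlier_sample[0]:
            outlier_shift = config.outlier_sample[1]
        # Draw plasma noise first; correlated assays reuse part of it in CSF.
        eps = {
            f: rng.normal(0.0, config.well_noise_sd, len(panels[f]))
            for f in ("plasma", "CSF")
        }
        plasma_eps = dict(zip(panels["plasma"], eps["plasma"]))
        for fluid in ("plasma", "CSF"):
            plate = layout[(sample, fluid)]
            poff = plate_offset[plate]
            for j, assay in enumerate(panels[fluid]):
                noise = eps[fluid][j]
                if fluid == "CSF" and assay in corr and assay in plasma_eps:
                    noise = rho * plasma_eps[assay] + np.sqrt(1 - rho**2) * noise
                ct = (
                    config.baseline_ct_mean
                    + assay_offset[assay]
                    + shifts[fluid].get((assay, group), 0.0)
                    + poff
                    + noise
                )
                if fluid == "CSF" and assay not in csf_ok:
                    ct += config.csf_shift
                if fluid == "plasma":
                    ct += outlier_shift
                if ct > config.censor_ct:
                    n_censored[fluid] += 1
                    ct = np.nan
                add_well(plate, sample, assay, "target", fluid, ct)
            spike_noise = rng.normal(0.0, config.well_noise_sd, len(config.spikein_ct))
            for k, spike in enumerate(sorted(config.spikein_ct)):
                ct = config.spikein_ct[spike] + poff + spike_noise[k]
                if ct > config.censor_ct:
                    ct = np.nan
                add_well(plate, sample, spike, spike, fluid, ct)
            add_well(plate, sample, "blank", "blank", fluid, np.nan)

    plates = []
    for p in plate_ids:
        wells = pd.DataFrame(plate_wells[p])
        if wells.empty:
            continue
        plates.append(RawPlate(plate_id=p, wells=wells))

    layout_df = pd.DataFrame(
        [{"sample_id": s, "fluid": f, "plate_id": p} for (s, f), p in layout.items()]
    )
    truth = GroundTruth(
        effects=_expected_effects(config),
        n_censored=n_censored,
        plate_layout=layout_df,
    )
    return plates, truth
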