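"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirseparate import CohortTable, CtMatrix, SimConfig, generate_cohort, simulate_raw_plates


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)


@pytest.fixture
def small_config():
    """A 4/4/4 cohort on a 12-plex dual-fluid panel, no dropout tiers."""
    return SimConfig(
        n_lrrk2=4,
        n_spd=4,
        n_hc=4,
        n_assays_plasma=12,
        n_assays_csf=12,
        baseline_ct_mean=28.0,
        baseline_ct_sd=2.0,
        low_abundance_fraction=0.0,
        plate_offset_sd=0.5,
        well_noise_sd=0.3,
        csf_shift=0.0,
        n_plates=3,
        seed=11,
    )


@pytest.fixture
def small_run(small_config):
    cohort = generate_cohort(small_config)
    plates, truth = simulate_raw_plates(cohort, small_config)
    return cohort, plates, truth


def make_ct_matrix(values, sample_ids=None, assay_ids=None, fluid="plasma"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i + 1:02d}" for i in range(n)]
    assay_ids = assay_ids or [f"miR-t{j + 1:02d}" for j in range(p)]
    return CtMatrix(pd.DataFrame(values, index=sample_ids, columns=assay_ids), fluid)


def make_cohort(groups: dict[str, list[str]]) -> CohortTable:
    rows = []
    for group, sample_ids in groups.items():
        for sid in sample_ids:
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "symptomatic": group == "sPD",
                    "has_plasma": True,
                    "has_csf": True,
                }
            )
    return CohortTable(pd.DataFrame(rows).set_index("sample_id"))
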