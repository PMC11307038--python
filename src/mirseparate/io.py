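"""Reading and writing the pipeline's delimited file formats.

All files are UTF-8 CSV with a header row. The raw-plate file is long
format (one well per row); undetected reactions are written as
``undetected`` and parsed back to missing. Several qPCR export dialects
are accepted on input: ``undetected``, ``Undetermined``, an empty cell, or
a sentinel Ct of 99 or more all mean "no specific amplification".
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ASSAY_CLASSES, FLUIDS, CohortTable, CtMatrix, RawPlate
from .exceptions import ParseError

MISSING_TOKENS = {"undetected", "undetermined", "na", "nan", ""}
SENTINEL_CT = 99.0

PLATE_COLUMNS = ["plate_id", "well", "sample_id", "assay_id", "assay_class", "fluid", "ct"]
SHEET_COLUMNS = ["sample_id", "group", "symptomatic", "fluid"]


def parse_ct(token: str) -> float:
    """Parse one Ct cell; returns NaN for any recognized missing dialect."""
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return np.nan
    value = float(tok)  # caller wraps failures with a line number
    return np.nan if value >= SENTINEL_CT else value


def write_raw_plates(plates: list[RawPlate], path) -> None:
    rows = []
    for plate in plates:
        w = plate.wells.copy()
        w.insert(0, "plate_id", plate.plate_id)
        rows.append(w)
    out = pd.concat(rows, ignore_index=True)[PLATE_COLUMNS]
    out["ct"] = out["ct"].map(lambda v: "undetected" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, index=False)


def write_sample_sheet(cohort: CohortTable, path) -> None:
    rows = []
    for sid, rec in cohort.table.iterrows():
        for fluid, flag in (("plasma", "has_plasma"), ("CSF", "has_csf")):
            if rec[flag]:
                rows.append(
                    {
                        "sample_id": sid,
                        "group": rec["group"],
                        "symptomatic": rec["symptomatic"],
                        "fluid": fluid,
                    }
                )
    pd.DataFrame(rows)[SHEET_COLUMNS].to_csv(path, index=False)


def read_sample_sheet(path) -> CohortTable:
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet lacks columns {sorted(missing)}")
    bad = set(sheet["fluid"]) - set(FLUIDS)
    if bad:
        raise ParseError(f"sample sheet has unknown fluids {sorted(bad)}")
    rows = {}
    for _, rec in sheet.iterrows():
        sid = rec["sample_id"]
        entry = rows.setdefault(
            sid,
            {
                "group": rec["group"],
                "symptomatic": bool(rec["symptomatic"]),
                "has_plasma": False,
                "has_csf": False,
            },
        )
        if entry["group"] != rec["group"]:
            raise ParseError(f"sample {sid} listed with conflicting groups")
        entry["has_plasma" if rec["fluid"] == "plasma" else "has_csf"] = True
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return CohortTable(table)


def read_raw_plates(path, sample_sheet) -> tuple[list[RawPlate], CohortTable]:
    """Parse a long-format raw-plate file against its sample sheet.

    Malformed rows raise :class:`ParseError` with the 1-based line number;
    wells referencing sample ids absent from the sheet are rejected;
    duplicate (sample, assay, fluid) target wells within a plate raise
    :class:`DuplicateWellError`.
    """
    cohort = read_sample_sheet(sample_sheet)
    known = set(cohort.sample_ids)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != PLATE_COLUMNS:
            raise ParseError(
                f"raw-plate file must have header {','.join(PLATE_COLUMNS)}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(PLATE_COLUMNS):
                raise ParseError(f"expected {len(PLATE_COLUMNS)} fields, got {len(row)}", lineno)
            rec = dict(zip(PLATE_COLUMNS, (c.strip() for c in row)))
            if rec["assay_class"] not in ASSAY_CLASSES:
                raise ParseError(f"unknown assay class {rec['assay_class']!r}", lineno)
            if rec["fluid"] not in FLUIDS:
                raise ParseError(f"unknown fluid {rec['fluid']!r}", lineno)
            if rec["sample_id"] not in known:
                raise ParseError(f"unknown sample id {rec['sample_id']!r}", lineno)
            try:
                rec["ct"] = parse_ct(rec["ct"])
            except ValueError:
                raise ParseError(f"unparseable Ct value {rec['ct']!r}", lineno) from None
            records.append(rec)
    if not records:
        raise ParseError("raw-plate file contains no wells")
    frame = pd.DataFrame(records)
    plates = [
        RawPlate(plate_id=pid, wells=grp.drop(columns="plate_id").reset_index(drop=True))
        for pid, grp in frame.groupby("plate_id", sort=True)
    ]
    return plates, cohort


def write_matrix(matrix: CtMatrix, path) -> None:
    """Wide per-fluid matrix: rows samples, columns assays, empty cell = missing."""
    matrix.values.to_csv(path, index_label="sample_id")


def read_matrix(path, fluid: str) -> CtMatrix:
    values = pd.read_csv(path, index_col="sample_id")
    return CtMatrix(values, fluid)


def write_ground_truth(truth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.effects.to_csv(outdir / "ground_truth_effects.csv", index=False)
    truth.plate_layout.to_csv(outdir / "plate_layout.csv", index=False)
    pd.DataFrame(
        [{"fluid": f, "n_censored": n} for f, n in sorted(truth.n_censored.items())]
    ).to_csv(outdir / "censored_wells.csv", index=False)
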