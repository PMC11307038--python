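"""Spike-in calibration, censoring and feature retention.

Reads the raw plates from step 01, verifies the spike-in controls,
removes interplate offsets with the UniSpike 3 calibration factors,
censors Ct > 40 and drops features missing in more than one individual
(per fluid). Writes the per-fluid calibrated matrices and QC tables.
"""

from pathlib import Path

from mirseparate import (
    apply_calibration,
    censor_and_filter,
    compute_calibration_factors,
    spike_in_qc,
)
from mirseparate.io import read_raw_plates, write_matrix

DATA = Path("results/data")
OUT = Path("results/calibrated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    plates, cohort = read_raw_plates(DATA / "raw_plates.csv", DATA / "sample_sheet.csv")
    qc = spike_in_qc(plates)
    qc.spike_checks.to_csv(OUT / "spike_qc.csv", index=False)
    print(f"spike-in QC: {int(qc.spike_checks['passed'].sum())}/{len(qc.spike_checks)} pass, "
          f"{len(qc.blank_violations)} blank violations")

    factors = compute_calibration_factors(plates)
    factors.factors.rename_axis("plate_id").to_csv(OUT / "calibration_factors.csv")
    print(f"calibration factors span {factors.factors.min():+.2f} .. {factors.factors.max():+.2f} Ct")

    for fluid, matrix in apply_calibration(plates, factors).items():
        filtered, report = censor_and_filter(matrix, cohort)
        write_matrix(filtered, OUT / f"matrix_{fluid}_filtered.csv")
        report.missing_by_group.to_csv(OUT / f"qc_missing_{fluid}.csv", index=False)
        n_flag = int(report.missing_by_group["balance_flag"].sum())
        print(
            f"{fluid}: {filtered.values.shape[1]}/{matrix.values.shape[1]} features retained, "
            f"{report.n_censored} wells censored, {n_flag} missingness-balance flags"
        )


if __name__ == "__main__":
    main()
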