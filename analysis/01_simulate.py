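"""Generate the synthetic study-condition cohort and its raw qPCR plates.

Writes the raw long-format plate file, the sample sheet and the ground
truth (planted effects, plate layout, censoring bookkeeping) under
results/data/. Every later step starts from these files, so the whole
analysis is reproducible from a single seed.
"""

from pathlib import Path

from mirseparate import generate_cohort, simulate_raw_plates
from mirseparate.io import write_ground_truth, write_raw_plates, write_sample_sheet
from mirseparate.synthetic import default_sim_config

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_sim_config(seed=SEED)
    cohort = generate_cohort(cfg)
    plates, truth = simulate_raw_plates(cohort, cfg)
    write_raw_plates(plates, OUT / "raw_plates.csv")
    write_sample_sheet(cohort, OUT / "sample_sheet.csv")
    write_ground_truth(truth, OUT)
    n_wells = sum(len(p.wells) for p in plates)
    print(f"cohort: {cohort.group_sizes().to_dict()}")
    print(f"{len(plates)} plates, {n_wells} wells; censored: {truth.n_censored}")
    print(f"wrote raw plates + sample sheet + ground truth -> {OUT}")


if __name__ == "__main__":
    main()
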