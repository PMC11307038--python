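"""Cross-biofluid integration: Pearson gate and multiplied features.

Correlates every CSF-detectable miRNA's CSF Ct against the same panel in
plasma, keeps pairs with two-tailed p < 0.05, and multiplies the paired
Ct values into new cross-fluid features for downstream models.
"""

from pathlib import Path

from mirseparate import build_multiplied_features, cross_fluid_correlation
from mirseparate.io import read_matrix

CAL = Path("results/calibrated")
OUT = Path("results/integration")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    csf = read_matrix(CAL / "matrix_CSF_filtered.csv", "CSF")
    plasma = read_matrix(CAL / "matrix_plasma_filtered.csv", "plasma")
    gate = cross_fluid_correlation(csf, plasma, alpha=0.05)
    gate.pairs.to_csv(OUT / "correlation_gate.csv", index=False)
    sel = gate.selected
    print(
        f"{gate.n_selected}/{len(gate.pairs)} pairs pass p<0.05"
        + (f", |r| {sel['r'].abs().min():.2f}-{sel['r'].abs().max():.2f}" if len(sel) else "")
    )
    mult = build_multiplied_features(gate, csf, plasma)
    mult.values.to_csv(OUT / "multiplied_features.csv", index_label="sample_id")
    print(f"multiplied matrix: {mult.values.shape[0]} samples x {mult.values.shape[1]} features")


if __name__ == "__main__":
    main()
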