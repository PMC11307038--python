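"""Calibration, censoring/retention filters, spike-in QC and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirseparate import (
    apply_calibration,
    censor_and_filter,
    compute_calibration_factors,
    simulate_raw_plates,
    generate_cohort,
    spike_in_qc,
)
from mirseparate.calibration import exact_missingness_balance
from mirseparate.datatypes import RawPlate
from mirseparate.exceptions import (
    CalibrationError,
    DuplicateWellError,
    EmptyPanelError,
    ParseError,
)
from mirseparate.io import read_raw_plates, write_raw_plates, write_sample_sheet

from conftest import make_cohort, make_ct_matrix


def plate_from_rows(plate_id, rows):
    cols = ["well", "sample_id", "assay_id", "assay_class", "fluid", "ct"]
    return RawPlate(plate_id, pd.DataFrame(rows, columns=cols))


def spike_row(well, ct, sample="S01"):
    return (well, sample, "unispike3", "unispike3", "plasma", ct)


class TestCalibrationFactors:
    def test_hand_arithmetic_two_plates(self):
        p1 = plate_from_rows("A", [spike_row("w1", 20.0)])
        p2 = plate_from_rows("B", [spike_row("w1", 22.0)])
        factors = compute_calibration_factors([p1, p2])
        assert factors.grand_mean == pytest.approx(21.0)
        assert factors["A"] == pytest.approx(-1.0)
        assert factors["B"] == pytest.approx(1.0)

    def test_homogeneous_plates_zero_factors(self):
        plates = [plate_from_rows(pid, [spike_row("w1", 21.5)]) for pid in "ABC"]
        factors = compute_calibration_factors(plates)
        assert np.allclose(factors.factors, 0.0)

    def test_shift_equivariance(self, small_run):
        """+3 on one plate moves that plate's factor up and the rest only
        through the pooled mean, so relative factors shift by exactly 3."""
        _, plates, _ = small_run
        base = compute_calibration_factors(plates)
        shifted = []
        for p in plates:
            w = p.wells.copy()
            if p.plate_id == plates[0].plate_id:
                w["ct"] = w["ct"] + 3.0
            shifted.append(RawPlate(p.plate_id, w))
        moved = compute_calibration_factors(shifted)
        delta = (moved.factors - base.factors).sort_index()
        others = delta.drop(plates[0].plate_id)
        # all unshifted plates move by the same grand-mean term ...
        assert np.allclose(others, others.iloc[0], atol=1e-9)
        # ... and the shifted plate sits exactly 3 cycles above them
        assert delta[plates[0].plate_id] - others.iloc[0] == pytest.approx(3.0, abs=1e-9)

    def test_missing_unispike3_is_an_error(self):
        bad = plate_from_rows("A", [("w1", "S01", "miR-x", "target", "plasma", 25.0)])
        with pytest.raises(CalibrationError, match="A"):
            compute_calibration_factors([bad])


class TestApplyCalibration:
    def test_zero_factors_identity_and_arithmetic(self):
        plate = plate_from_rows(
            "A",
            [
                ("w1", "S01", "miR-a", "target", "plasma", 25.0),
                spike_row("w2", 21.0),
            ],
        )
        factors = compute_calibration_factors([plate])
        mats = apply_calibration([plate], factors)
        assert mats["plasma"].values.loc["S01", "miR-a"] == pytest.approx(25.0)

        # a +1 factor subtracts one cycle
        plate2 = plate_from_rows(
            "B",
            [
                ("w1", "S02", "miR-a", "target", "plasma", 25.0),
                spike_row("w2", 22.0, "S02"),
            ],
        )
        mats = apply_calibration([plate, plate2], compute_calibration_factors([plate, plate2]))
        assert mats["plasma"].values.loc["S02", "miR-a"] == pytest.approx(24.5)
        assert mats["plasma"].values.loc["S01", "miR-a"] == pytest.approx(25.5)

    def test_plate_shift_invariance(self, small_run, rng):
        """Per-plate shifts calibrate away exactly once the unidentifiable
        common component (the pooled-spike-weighted mean shift) is removed;
        an uncentered shift moves every cell by exactly that constant."""
        _, plates, _ = small_run
        base = apply_calibration(plates, compute_calibration_factors(plates))
        raw = {p.plate_id: rng.normal(0, 5) for p in plates}
        n_spikes = {p.plate_id: len(p.spike_wells("unispike3")) for p in plates}
        total = sum(n_spikes.values())
        pooled_mean = sum(raw[pid] * n_spikes[pid] for pid in raw) / total

        def shift_plates(shifts):
            out = []
            for p in plates:
                w = p.wells.copy()
                w["ct"] = w["ct"] + shifts[p.plate_id]
                out.append(RawPlate(p.plate_id, w))
            return apply_calibration(out, compute_calibration_factors(out))

        centered = shift_plates({pid: c - pooled_mean for pid, c in raw.items()})
        for fluid in base:
            pd.testing.assert_frame_equal(
                base[fluid].values, centered[fluid].values, atol=1e-9, rtol=0
            )
        uncentered = shift_plates(raw)
        for fluid in base:
            diff = uncentered[fluid].values - base[fluid].values
            assert np.allclose(diff.to_numpy()[base[fluid].mask.to_numpy()], pooled_mean, atol=1e-9)

    def test_idempotence(self, small_run):
        _, plates, _ = small_run
        factors = compute_calibration_factors(plates)
        calibrated_plates = []
        for p in plates:
            w = p.wells.copy()
            w["ct"] = w["ct"] - factors[p.plate_id]
            calibrated_plates.append(RawPlate(p.plate_id, w))
        refactors = compute_calibration_factors(calibrated_plates)
        assert np.allclose(refactors.factors, 0.0, atol=1e-9)
        first = apply_calibration(plates, factors)
        second = apply_calibration(calibrated_plates, refactors)
        for fluid in first:
            pd.testing.assert_frame_equal(first[fluid].values, second[fluid].values, atol=1e-9, rtol=0)


class TestCensorAndFilter:
    def cohort30(self):
        return make_cohort(
            {
                "LRRK2_MC": [f"L{i:02d}" for i in range(10)],
                "sPD": [f"P{i:02d}" for i in range(10)],
                "HC": [f"H{i:02d}" for i in range(10)],
            }
        )

    def test_retention_rule_boundary(self):
        cohort = self.cohort30()
        values = np.full((30, 3), 30.0)
        values[0, 0] = np.nan  # missing in 1 -> retained
        values[0, 1] = np.nan
        values[1, 1] = np.nan  # missing in 2 -> dropped
        m = make_ct_matrix(values, sample_ids=cohort.sample_ids)
        filtered, report = censor_and_filter(m, cohort)
        assert list(filtered.values.columns) == ["miR-t01", "miR-t03"]
        assert report.dropped_features == ["miR-t02"]

    def test_strict_censoring_rule_keeps_exactly_40(self):
        cohort = self.cohort30()
        values = np.full((30, 2), 30.0)
        values[0, 0] = 40.0  # exactly the limit: retained
        values[0, 1] = 40.0001  # strictly above: censored
        m = make_ct_matrix(values, sample_ids=cohort.sample_ids)
        filtered, report = censor_and_filter(m, cohort, censor_ct=40.0)
        assert filtered.values.loc[cohort.sample_ids[0], "miR-t01"] == pytest.approx(40.0)
        assert np.isnan(filtered.values.loc[cohort.sample_ids[0], "miR-t02"])
        assert report.n_censored == 1

    def test_no_censoring_identity(self):
        cohort = self.cohort30()
        m = make_ct_matrix(np.full((30, 4), 25.0), sample_ids=cohort.sample_ids)
        filtered, report = censor_and_filter(m, cohort)
        pd.testing.assert_frame_equal(filtered.values, m.values)
        assert report.n_censored == 0

    def test_filter_monotone_in_max_missing(self):
        cohort = self.cohort30()
        rng = np.random.default_rng(5)
        values = np.full((30, 12), 30.0)
        holes = rng.random((30, 12)) < 0.08
        values[holes] = np.nan
        m = make_ct_matrix(values, sample_ids=cohort.sample_ids)
        kept = []
        for k in (0, 1, 2, 3):
            try:
                kept.append(censor_and_filter(m, cohort, max_missing_individuals=k)[0].values.shape[1])
            except EmptyPanelError:
                kept.append(0)
        assert kept == sorted(kept)

    def test_empty_panel_error(self):
        cohort = self.cohort30()
        values = np.full((30, 2), np.nan)
        m = make_ct_matrix(values, sample_ids=cohort.sample_ids)
        with pytest.raises(EmptyPanelError):
            censor_and_filter(m, cohort)

    def test_censored_count_matches_generator_bookkeeping(self, small_config):
        """Censoring at 40 in the pipeline reproduces the generator's own count."""
        open_cfg = small_config.with_(censor_ct=99.0, baseline_ct_mean=36.0, baseline_ct_sd=3.0)
        closed_cfg = small_config.with_(censor_ct=40.0, baseline_ct_mean=36.0, baseline_ct_sd=3.0)
        cohort = generate_cohort(open_cfg)
        plates_open, _ = simulate_raw_plates(cohort, open_cfg)
        _, truth_closed = simulate_raw_plates(cohort, closed_cfg)
        mats = apply_calibration(plates_open, compute_calibration_factors(plates_open))
        # compare pre-calibration raw counts: censor the raw target wells directly
        wells = pd.concat([p.wells for p in plates_open])
        targets = wells[wells["assay_class"] == "target"]
        for fluid in ("plasma", "CSF"):
            raw_over = int((targets.loc[targets["fluid"] == fluid, "ct"] > 40.0).sum())
            assert raw_over == truth_closed.n_censored[fluid]


class TestMissingnessBalance:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_fisher_for_two_groups(self, seed):
        rng = np.random.default_rng(seed)
        n = pd.Series({"A": int(rng.integers(3, 12)), "B": int(rng.integers(3, 12))})
        miss = pd.Series({g: int(rng.integers(0, n[g] + 1)) for g in n.index})
        table = [[miss["A"], n["A"] - miss["A"]], [miss["B"], n["B"] - miss["B"]]]
        _, expected = stats.fisher_exact(table)
        got = exact_missingness_balance(miss, n)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_no_missing_gives_p_one(self):
        assert exact_missingness_balance(pd.Series({"A": 0}), pd.Series({"A": 5, "B": 5})) == 1.0

    def test_extreme_imbalance_is_small(self):
        n = pd.Series({"A": 10, "B": 10, "C": 10})
        p = exact_missingness_balance(pd.Series({"A": 8, "B": 0, "C": 0}), n)
        assert p < 0.01


class TestSpikeInQc:
    def test_clean_run_no_violations(self, small_run):
        _, plates, _ = small_run
        report = spike_in_qc(plates)
        assert report.blank_violations.empty
        assert report.spike_checks["passed"].all()

    def test_detected_blank_flags_plate(self):
        plate = plate_from_rows(
            "A",
            [
                spike_row("w1", 21.0),
                ("w2", "S01", "blank", "blank", "plasma", 35.0),
            ],
        )
        report = spike_in_qc([plate])
        assert list(report.blank_violations["plate_id"]) == ["A"]

    def test_spike_outside_window_fails(self):
        plate = plate_from_rows(
            "A",
            [spike_row("w1", 21.0), ("w2", "S01", "unispike2", "unispike2", "plasma", 30.0)],
        )
        report = spike_in_qc([plate], thresholds={"unispike2": (22.0, 26.0)})
        row = report.spike_checks.query("spike == 'unispike2'").iloc[0]
        assert not row["passed"]


class TestRawPlateIo:
    def test_write_read_round_trip(self, small_run, tmp_path):
        cohort, plates, _ = small_run
        write_raw_plates(plates, tmp_path / "plates.csv")
        write_sample_sheet(cohort, tmp_path / "sheet.csv")
        back, cohort2 = read_raw_plates(tmp_path / "plates.csv", tmp_path / "sheet.csv")
        assert [p.plate_id for p in back] == [p.plate_id for p in plates]
        for a, b in zip(plates, back):
            left = a.wells.reset_index(drop=True)
            right = b.wells[left.columns].reset_index(drop=True)
            pd.testing.assert_frame_equal(left, right, atol=1e-6, rtol=0)
        pd.testing.assert_frame_equal(cohort.table, cohort2.table.loc[cohort.table.index])

    def test_undetermined_parses_as_missing_not_zero(self, tmp_path):
        (tmp_path / "sheet.csv").write_text(
            "sample_id,group,symptomatic,fluid\nS01,sPD,True,plasma\n"
        )
        (tmp_path / "plates.csv").write_text(
            "plate_id,well,sample_id,assay_id,assay_class,fluid,ct\n"
            "A,w1,S01,miR-a,target,plasma,Undetermined\n"
            "A,w2,S01,unispike3,unispike3,plasma,21.0\n"
        )
        plates, _ = read_raw_plates(tmp_path / "plates.csv", tmp_path / "sheet.csv")
        ct = plates[0].target_wells["ct"].iloc[0]
        assert np.isnan(ct)

    def test_malformed_row_reports_line_number(self, tmp_path):
        (tmp_path / "sheet.csv").write_text(
            "sample_id,group,symptomatic,fluid\nS01,sPD,True,plasma\n"
        )
        (tmp_path / "plates.csv").write_text(
            "plate_id,well,sample_id,assay_id,assay_class,fluid,ct\n"
            "A,w1,S01,miR-a,target,plasma,25.0\n"
            "A,w2,S01,miR-b,target,plasma,not-a-number\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_raw_plates(tmp_path / "plates.csv", tmp_path / "sheet.csv")

    def test_unknown_sample_rejected(self, tmp_path):
        (tmp_path / "sheet.csv").write_text(
            "sample_id,group,symptomatic,fluid\nS01,sPD,True,plasma\n"
        )
        (tmp_path / "plates.csv").write_text(
            "plate_id,well,sample_id,assay_id,assay_class,fluid,ct\n"
            "A,w1,GHOST,miR-a,target,plasma,25.0\n"
        )
        with pytest.raises(ParseError, match="GHOST"):
            read_raw_plates(tmp_path / "plates.csv", tmp_path / "sheet.csv")

    def test_duplicate_well_rejected(self):
        rows = [
            ("w1", "S01", "miR-a", "target", "plasma", 25.0),
            ("w2", "S01", "miR-a", "target", "plasma", 26.0),
        ]
        with pytest.raises(DuplicateWellError):
            plate_from_rows("A", rows)
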