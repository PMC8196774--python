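"""Median-difference RETSPL calibration and agreement statistics."""

import numpy as np
import pandas as pd
import pytest

from puretone import calibrate as cal
from puretone.core import TEST_FREQUENCIES, RetsplTable
from puretone.listeners import CohortSpec, balanced_calibration_cohort, sample_cohort


def pairs(rows):
    return cal.PairedMeasurements(
        pd.DataFrame(rows, columns=["ear_id", "freq_hz", "audiometer_dbhl", "device_dbhl"])
    )


def full_coverage_pairs(offset=0.0, n_ears=4):
    rows = []
    for e in range(n_ears):
        for f in TEST_FREQUENCIES:
            rows.append([f"E{e}", f, 10.0 + e, 10.0 + e + offset])
    return pairs(rows)


class TestPairedMeasurements:
    def test_duplicate_cells_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pairs([["E0", 1000, 10, 10], ["E0", 1000, 15, 15]])

    def test_no_response_rows_excluded_and_counted(self):
        pm = pairs([["E0", 1000, 10, np.nan], ["E1", 1000, 15, 20]])
        assert len(pm) == 1
        assert pm.n_no_response == 1

    def test_nr_text_cells_parse_as_no_response(self, tmp_path):
        path = tmp_path / "pairs.csv"
        path.write_text(
            "ear_id,freq_hz,audiometer_dbhl,device_dbhl\nE0,1000,10,NR\nE1,1000,5,10\n"
        )
        pm = cal.PairedMeasurements.from_csv(path)
        assert len(pm) == 1 and pm.n_no_response == 1

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError, match="range|\\[-10"):
            pairs([["E0", 1000, 150, 10]])


class TestMedianDifference:
    def test_single_pair(self):
        assert cal.median_threshold_difference(pairs([["E0", 500, 10, 20]])) == {500: -10.0}

    def test_even_count_midpoint(self):
        pm = pairs([["E0", 500, 10, 20], ["E1", 500, 15, 20],
                    ["E2", 500, 20, 20], ["E3", 500, 27, 20]])
        # diffs {-10, -5, 0, 7} -> midpoint of -5 and 0
        assert cal.median_threshold_difference(pm) == {500: -2.5}

    def test_brute_force_median(self):
        pm = pairs([["E0", 500, 10, 20], ["E1", 500, 15, 20], ["E2", 500, 20, 20]])
        assert cal.median_threshold_difference(pm) == {500: -5.0}

    def test_identical_columns_give_zero(self):
        med = cal.median_threshold_difference(full_coverage_pairs())
        assert med == {f: 0.0 for f in TEST_FREQUENCIES}

    def test_invariance_row_permutation_and_shift(self):
        pm = full_coverage_pairs(offset=3.0)
        base = cal.median_threshold_difference(pm)
        shuffled = cal.PairedMeasurements(
            pm.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        assert cal.median_threshold_difference(shuffled) == base
        shifted_df = pm.data.copy()
        shifted_df[["audiometer_dbhl", "device_dbhl"]] += 7.0
        assert cal.median_threshold_difference(cal.PairedMeasurements(shifted_df)) == base

    def test_frequency_without_valid_pairs_is_error(self):
        pm = pairs([["E0", 500, 10, 12], ["E1", 1000, np.nan, 12]])
        with pytest.raises(ValueError, match="1000"):
            cal.median_threshold_difference(pm)


class TestCorrectRetspl:
    def test_v1_to_v2_consistent_example(self, retspl_tables):
        """A median difference of -10 dB at 250 Hz moves the initial
        estimate 11.8 to the calibrated 1.8 dB SPL."""
        old = retspl_tables["HearTest v1"]
        med = {f: 0.0 for f in TEST_FREQUENCIES}
        med[250] = 10.0
        corrected = cal.correct_retspl(old, med)
        assert corrected.retspl(250) == pytest.approx(1.8)

    def test_zero_median_is_identity(self, retspl_tables):
        old = retspl_tables["HearTest v1"]
        corrected = cal.correct_retspl(old, {f: 0.0 for f in TEST_FREQUENCIES})
        assert corrected.entries == old.entries

    def test_missing_frequency_is_error(self, retspl_tables):
        with pytest.raises(ValueError, match="8000"):
            cal.correct_retspl(retspl_tables["HearTest v1"],
                               {f: 0.0 for f in TEST_FREQUENCIES[:-1]})


class TestSpearman:
    def test_perfectly_monotone(self):
        pm = pairs([[f"E{i}", 1000, i * 5, i * 5 + 3] for i in range(5)])
        rho, _p = cal.spearman_rank_correlation(pm)
        assert rho == pytest.approx(1.0)

    def test_reversed_ordering(self):
        pm = pairs([[f"E{i}", 1000, i * 5, 100 - i * 5] for i in range(5)])
        rho, _p = cal.spearman_rank_correlation(pm)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        pm = pairs([["E0", 1000, 1, 2], ["E1", 1000, 2, 1], ["E2", 1000, 3, 3]])
        rho, p = cal.spearman_rank_correlation(pm)
        assert rho == pytest.approx(0.5)
        # exact permutation over 3! orderings: every permutation of three
        # distinct ranks has |rho| in {0.5, 1.0}, so all 6 reach |0.5|
        assert p == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            cal.spearman_rank_correlation(pairs([["E0", 1000, 1, 2], ["E1", 1000, 2, 3]]))

    def test_large_sample_p_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        x = rng.normal(10, 5, 40)
        y = x + rng.normal(0, 3, 40)
        pm = pairs([[f"E{i}", 1000, round(a, 1), round(b, 1)]
                    for i, (a, b) in enumerate(zip(x, y))])
        rho, p = cal.spearman_rank_correlation(pm)
        ref = stats.spearmanr(pm.data["audiometer_dbhl"], pm.data["device_dbhl"])
        assert rho == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


class TestMAE:
    def test_identical_columns_zero(self):
        mae = cal.mean_absolute_error(full_coverage_pairs())
        assert all(m == 0.0 and sd == 0.0 for m, sd in mae.values())

    def test_constant_offset(self):
        mae = cal.mean_absolute_error(full_coverage_pairs(offset=5.0))
        for m, sd in mae.values():
            assert m == pytest.approx(5.0)
            assert sd == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        pm = pairs([["E0", 500, 10, 10], ["E1", 500, 10, 20]])
        mae = cal.mean_absolute_error(pm)
        assert mae[500][0] == pytest.approx(5.0)


class TestDeviceSpread:
    def test_packaged_table_overall_spread(self, device_table):
        spread, overall = cal.device_output_spread(device_table)
        assert overall == pytest.approx(2.0)
        top = spread.loc[spread["spread_db"].idxmax()]
        assert top["freq_hz"] == 250 and top["channel"] == "L"

    def test_identical_devices_zero_spread(self, device_table):
        df = device_table.data.copy()
        freq_cols = [f"f{f}" for f in TEST_FREQUENCIES]
        df[freq_cols] = df.groupby("channel")[freq_cols].transform("mean")
        _, overall = cal.device_output_spread(cal.DeviceOutputTable(df))
        assert overall == pytest.approx(0.0)

    def test_injected_difference_detected(self, device_table):
        df = device_table.data.copy()
        df.loc[0, "f1000"] += 3.0  # widen one cell well past the rest
        _, overall = cal.device_output_spread(cal.DeviceOutputTable(df))
        left = df[df["channel"] == "L"]["f1000"]
        assert overall == pytest.approx(left.max() - left.min())

    def test_single_device_is_error(self, device_table):
        df = device_table.data[device_table.data["device"] == "iPhone XR"]
        with pytest.raises(ValueError):
            cal.device_output_spread(cal.DeviceOutputTable(df))


class TestSimulationRecovery:
    def test_calibration_recovers_injected_error(self, retspl_tables):
        """End-to-end: inject a per-frequency RETSPL error, run the paired
        study on a deterministic 40-ear cohort, correct the table; the
        corrected RETSPLs match truth within 2.5 dB and MAE improves."""
        old = retspl_tables["HearTest v1"]
        cohort = balanced_calibration_cohort(n_listeners=20)
        error = {250: -12.0, 500: -5.0, 1000: 0.0, 2000: 4.0, 4000: 9.0, 8000: 15.0}
        pm = cal.simulate_paired_measurements(cohort, error)
        report = cal.calibration_report(pm, old)
        truth = {f: old.retspl(f) + error[f] for f in TEST_FREQUENCIES}
        for f in TEST_FREQUENCIES:
            assert abs(report["corrected"].retspl(f) - truth[f]) <= 2.5
        # residual error after correction, re-simulated
        residual = {
            f: truth[f] - report["corrected"].retspl(f) for f in TEST_FREQUENCIES
        }
        pm_post = cal.simulate_paired_measurements(cohort, residual)
        mae_pre = cal.mean_absolute_error(pm)
        mae_post = cal.mean_absolute_error(pm_post)
        for f in TEST_FREQUENCIES:
            assert mae_post[f][0] <= mae_pre[f][0]

    def test_rho_improves_after_calibration(self, retspl_tables):
        """Large injected errors destroy the pooled rank correlation;
        correcting the table restores it."""
        cohort = sample_cohort(
            CohortSpec(n_listeners=20, model="step", threshold_sd=5.0, seed=8)
        )
        error = {250: 14.0, 500: -12.0, 1000: 10.0, 2000: -15.0, 4000: 12.0, 8000: -10.0}
        pm_pre = cal.simulate_paired_measurements(cohort, error)
        rho_pre, _ = cal.spearman_rank_correlation(pm_pre)
        med = cal.median_threshold_difference(pm_pre)
        residual = {f: error[f] + med[f] for f in TEST_FREQUENCIES}
        pm_post = cal.simulate_paired_measurements(cohort, residual)
        rho_post, _ = cal.spearman_rank_correlation(pm_post)
        assert rho_post > rho_pre


def test_report_text_renders(retspl_tables):
    pm = full_coverage_pairs(offset=2.0)
    report = cal.calibration_report(pm, retspl_tables["HearTest v1"])
    text = cal.format_calibration_report(report)
    assert "Spearman rho" in text and "250" in text
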