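"""Dataset reading, validity parsing, intensity standardization, cohorts."""

import numpy as np
import pandas as pd
import pytest

from memdyn.ingest import (
    cohort_descriptors,
    feature_columns,
    parse_validity,
    read_dataset,
    standardize_intensities,
    write_csv_triplet,
)


class TestReadDataset:
    def test_csv_triplet_round_trip(self, small_table, tmp_path):
        table, _ = small_table
        write_csv_triplet(table, tmp_path)
        back = read_dataset(tmp_path, "csv-triplet")
        feats = feature_columns(table)
        assert feature_columns(back) == feats
        pd.testing.assert_frame_equal(
            back[feats + ["cell_speed", "dynamic_cell_area", "cmd"]],
            table[feats + ["cell_speed", "dynamic_cell_area", "cmd"]],
        )

    def test_misaligned_sheets_rejected(self, small_table, tmp_path):
        table, _ = small_table
        write_csv_triplet(table, tmp_path)
        idx = pd.read_csv(tmp_path / "index.csv")
        idx.iloc[:-1].to_csv(tmp_path / "index.csv", index=False)
        with pytest.raises(ValueError, match="misaligned"):
            read_dataset(tmp_path, "csv-triplet")

    def test_missing_process_column_rejected(self, small_table, tmp_path):
        table, _ = small_table
        write_csv_triplet(table, tmp_path)
        proc = pd.read_csv(tmp_path / "processes.csv").drop(columns=["cmd"])
        proc.to_csv(tmp_path / "processes.csv", index=False)
        with pytest.raises(ValueError, match="required columns"):
            read_dataset(tmp_path, "csv-triplet")

    def test_spreadsheet_dialect_with_loose_headers(self, tmp_path):
        n = 10
        path = tmp_path / "ds.xlsx"
        with pd.ExcelWriter(path) as xl:
            pd.DataFrame({"Feat A": np.arange(n), "Feat B": np.ones(n)}).to_excel(
                xl, sheet_name="features", index=False
            )
            pd.DataFrame(
                {
                    "Cell Speed": np.linspace(0.1, 1, n),
                    "Protrusion Pixels": np.arange(n),
                    "Retraction Pixels": np.arange(n),
                    "Short-lived Pixels": np.arange(n),
                    "Dynamic Cell Area": np.linspace(50, 90, n),
                    "CMD": np.zeros(n),
                }
            ).to_excel(xl, sheet_name="processes", index=False)
            pd.DataFrame(
                {
                    "Experiment Date": ["d1"] * n,
                    "Cell Trace": ["c1"] * n,
                    "Frame Number": np.arange(1, n + 1),
                }
            ).to_excel(xl, sheet_name="index", index=False)
        table = read_dataset(path, "s1-spreadsheet")
        assert len(table) == n
        assert {"cell_speed", "cmd", "experiment_id", "cell_trace_id"} <= set(table.columns)
        assert feature_columns(table) == ["Feat A", "Feat B"]


class TestParseValidity:
    @staticmethod
    def trace(frames):
        return pd.DataFrame(
            {"cell_trace_id": "c1", "frame_number": frames, "x": 0.0}
        )

    def test_contiguous_trace_keeps_interior(self):
        out = parse_validity(self.trace(range(1, 11)))
        assert int(out["valid"].sum()) == 8
        assert not out.loc[out["frame_number"].isin([1, 10]), "valid"].any()

    def test_gap_adjacent_frames_excluded(self):
        out = parse_validity(self.trace([1, 2, 3, 5, 6, 7]))
        assert out.loc[out["valid"], "frame_number"].tolist() == [2, 6]

    def test_idempotent_on_already_valid_interior(self, small_table):
        table, _ = small_table
        once = parse_validity(table)
        twice = parse_validity(once)
        assert (once["valid"] == twice["valid"]).all()


class TestStandardizeIntensities:
    @staticmethod
    def build(ref_median, n=40):
        # 2 tiny reference CMACs (below 3rd area percentile) + larger ones
        areas = np.concatenate([[0.16, 0.18], np.linspace(0.5, 3.0, n - 2)])
        inten = np.concatenate([[ref_median, ref_median], np.full(n - 2, 100.0)])
        return pd.DataFrame(
            {"experiment_id": "e1", "area": areas, "paxillin": inten}
        )

    def test_division_by_reference_median(self):
        out = standardize_intensities(self.build(50.0), ["paxillin"], percentile_cut=5)
        assert out["paxillin"].iloc[-1] == pytest.approx(2.0)

    def test_reference_objects_become_unity(self):
        df = self.build(50.0)
        df["paxillin"] = 50.0
        out = standardize_intensities(df, ["paxillin"], percentile_cut=5)
        assert np.allclose(out["paxillin"], 1.0)

    def test_experiments_standardized_independently(self):
        a = self.build(50.0)
        b = self.build(25.0)
        b["experiment_id"] = "e2"
        out = standardize_intensities(pd.concat([a, b], ignore_index=True),
                                      ["paxillin"], percentile_cut=5)
        va = out[out["experiment_id"] == "e1"]["paxillin"].iloc[-1]
        vb = out[out["experiment_id"] == "e2"]["paxillin"].iloc[-1]
        assert vb == pytest.approx(2 * va)

    def test_idempotence(self):
        df = self.build(50.0)
        once = standardize_intensities(df, ["paxillin"], percentile_cut=5)
        twice = standardize_intensities(once, ["paxillin"], percentile_cut=5)
        assert np.allclose(once["paxillin"], twice["paxillin"])


class TestCohortDescriptors:
    @staticmethod
    def cohort(values):
        return pd.DataFrame(
            {
                "cell_trace_id": "c1",
                "frame_number": 1,
                "feat": values,
                "area": 1.0,
                "lifetime": 10.0,
            }
        )

    def test_worked_example_exact_quartiles(self):
        """{2,4,8} under type-1 quantiles: QD=3, QS=-1/3, CoV=0.75."""
        out = cohort_descriptors(self.cohort([2, 4, 8]), ["feat"], method="inverted_cdf")
        row = out.iloc[0]
        assert (row["feat_q1"], row["feat_median"], row["feat_q3"]) == (2, 4, 8)
        assert row["feat_QD"] == pytest.approx(3.0)
        assert row["feat_QS"] == pytest.approx(-1 / 3)
        assert row["feat_CoV"] == pytest.approx(0.75)

    def test_symmetric_cohort_has_zero_skewness(self):
        out = cohort_descriptors(self.cohort([1, 2, 3]), ["feat"])
        assert out.iloc[0]["feat_QS"] == pytest.approx(0.0)

    def test_matches_brute_force_quartiles(self, rng):
        values = rng.gamma(2.0, 3.0, size=200)
        out = cohort_descriptors(self.cohort(values), ["feat"]).iloc[0]
        q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # same linear rule
        qd = (q3 - q1) / 2
        assert out["feat_QD"] == pytest.approx(qd)
        assert out["feat_QS"] == pytest.approx((q2 - (q1 + q3) / 2) / qd)
        assert out["feat_CoV"] == pytest.approx(qd / q2)
        assert out["total_area"] == pytest.approx(200.0)
        assert out["mean_lifetime"] == pytest.approx(10.0)

    def test_order_invariance(self, rng):
        values = rng.normal(5, 2, size=50)
        a = cohort_descriptors(self.cohort(values), ["feat"])
        b = cohort_descriptors(self.cohort(values[::-1]), ["feat"])
        pd.testing.assert_frame_equal(a, b)

    def test_shift_and_scale_invariances(self, rng):
        values = rng.lognormal(0, 0.5, size=80)
        base = cohort_descriptors(self.cohort(values), ["feat"]).iloc[0]
        shifted = cohort_descriptors(self.cohort(values + 7), ["feat"]).iloc[0]
        scaled = cohort_descriptors(self.cohort(values * 3), ["feat"]).iloc[0]
        assert shifted["feat_QD"] == pytest.approx(base["feat_QD"])  # QD shift-invariant
        assert scaled["feat_CoV"] == pytest.approx(base["feat_CoV"])  # CoV scale-invariant

    def test_degenerate_cohorts_flagged(self):
        out = cohort_descriptors(self.cohort([5, 5, 5, 5]), ["feat"]).iloc[0]
        assert np.isnan(out["feat_QS"])  # QD = 0
        out0 = cohort_descriptors(self.cohort([-1, 0, 1]), ["feat"]).iloc[0]
        assert np.isnan(out0["feat_CoV"])  # median = 0

    def test_literal_formula_switch(self):
        out = cohort_descriptors(
            self.cohort([2, 4, 8]), ["feat"], method="inverted_cdf", literal_formulas=True
        ).iloc[0]
        assert out["feat_QD"] == pytest.approx(12.0)  # 2(q3-q1)
        assert out["feat_QS"] == pytest.approx(4 - 6 / 24)  # q2-(q3-q1)/(2*QD)
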