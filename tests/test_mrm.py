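"""Transition aggregation, class summaries, panels and concordance."""

import io

import numpy as np
import pandas as pd
import pytest

from glutenscan.errors import FormatError, ValidationError
from glutenscan.mrm import (
    default_elisa_table,
    default_wheat_markers,
    elisa_concordance,
    heatmap_matrix,
    net_hordein,
    quantify_peptides,
    read_transition_report,
    summarise_classes,
    wheat_panel,
)


def table(rows):
    """Build a measurements frame from (sample, rep, pep, mod, trans, area)."""
    return pd.DataFrame(
        rows,
        columns=["sample_id", "replicate", "peptide_sequence", "mod_state",
                 "transition_id", "peak_area"],
    )


def rep_rows(sample, rep, pep, areas, mod="none"):
    return [
        (sample, rep, pep, mod, f"t{i + 1}", a) for i, a in enumerate(areas)
    ]


class TestReadTransitionReport:
    def test_three_transitions_give_three_records(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,replicate,peptide_sequence,transition_id,peak_area\n"
            "S1,1,ELQESSLEACR,t1,100\nS1,1,ELQESSLEACR,t2,200\nS1,1,ELQESSLEACR,t3,300\n"
        )
        df = read_transition_report(p)
        assert len(df) == 3
        assert df["mod_state"].eq("none").all()

    def test_column_map_resolves_header_variants(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "Sample,Rep,Peptide,Transition,TotalArea\nS1,1,AAAAK,t1,5\n"
        )
        df = read_transition_report(
            p,
            column_map={
                "sample_id": "Sample", "replicate": "Rep",
                "peptide_sequence": "Peptide", "transition_id": "Transition",
                "peak_area": "TotalArea",
            },
        )
        assert df.loc[0, "peak_area"] == 5.0

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("sample_id,replicate,peptide_sequence,transition_id\nS1,1,A,t1\n")
        with pytest.raises(FormatError, match="peak_area"):
            read_transition_report(p)

    def test_negative_area_reports_row_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,replicate,peptide_sequence,transition_id,peak_area\n"
            "S1,1,AAAAK,t1,10\nS1,1,AAAAK,t2,-5\n"
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_transition_report(p)

    def test_na_areas_are_missing_not_zero(self, tmp_path, caplog):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,replicate,peptide_sequence,transition_id,peak_area\n"
            "S1,1,AAAAK,t1,10\nS1,1,AAAAK,t2,#N/A\n"
        )
        with caplog.at_level("WARNING"):
            df = read_transition_report(p)
        assert len(df) == 1 and "missing" in caplog.text

    def test_duplicate_measurement_key_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "sample_id,replicate,peptide_sequence,transition_id,peak_area\n"
            "S1,1,AAAAK,t1,10\nS1,1,AAAAK,t1,11\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_transition_report(p)


class TestQuantifyPeptides:
    def test_transitions_sum_within_a_replicate(self):
        q = quantify_peptides(table(rep_rows("S1", 1, "AAAAK", [100, 200, 300])))
        assert q.loc[0, "summed_area"] == 600

    def test_oxidised_and_reduced_met_forms_merge(self):
        rows = rep_rows("S1", 1, "MAAAK", [50, 50, 50], mod="reduced") + rep_rows(
            "S1", 1, "MAAAK", [10, 10, 10], mod="met_oxidised"
        )
        q = quantify_peptides(table(rows))
        assert q.loc[0, "summed_area"] == 180

    def test_identical_replicates_have_zero_cv(self):
        rows = [r for rep in range(1, 5) for r in rep_rows("S1", rep, "AAAAK", [40, 30, 30])]
        q = quantify_peptides(table(rows))
        assert q.loc[0, "summed_area"] == 100 and q.loc[0, "cv"] == 0

    def test_cv_uses_sample_sd_over_mean(self):
        sums = [90, 100, 110, 100]
        rows = [r for rep, s in enumerate(sums, 1) for r in rep_rows("S1", rep, "AAAAK", [s])]
        q = quantify_peptides(table(rows))
        # hand oracle: SD([90,100,110,100], n-1) / 100 = 8.1650/100
        assert q.loc[0, "cv"] == pytest.approx(0.081650, abs=1e-6)

    def test_missing_replicates_padded_with_zero_and_flagged(self, caplog):
        rows = rep_rows("S1", 1, "AAAAK", [100]) + rep_rows("S1", 2, "AAAAK", [100])
        rows += rep_rows("S1", 1, "CCCCK", [50]) + rep_rows("S1", 2, "CCCCK", [50])
        rows += rep_rows("S1", 3, "CCCCK", [50]) + rep_rows("S1", 4, "CCCCK", [50])
        with caplog.at_level("WARNING"):
            q = quantify_peptides(table(rows))
        a = q.set_index("peptide_sequence")
        assert a.loc["AAAAK", "summed_area"] == 50  # (100+100+0+0)/4
        assert "missing" in caplog.text

    def test_detection_threshold(self):
        rows = rep_rows("S1", 1, "AAAAK", [1.0])
        q = quantify_peptides(table(rows), detection_threshold=5.0)
        assert not q.loc[0, "detected"]

    def test_split_and_merge_equals_whole(self):
        rows = [
            r
            for rep in range(1, 5)
            for pep in ("AAAAK", "CCCCK")
            for r in rep_rows("S1", rep, pep, [10 * rep, 20, 30])
        ]
        df = table(rows)
        whole = quantify_peptides(df)
        parts = pd.concat(
            [df[df.peptide_sequence == "AAAAK"], df[df.peptide_sequence == "CCCCK"]]
        )
        again = quantify_peptides(parts)
        pd.testing.assert_frame_equal(
            whole.sort_values(["sample_id", "peptide_sequence"]).reset_index(drop=True),
            again.sort_values(["sample_id", "peptide_sequence"]).reset_index(drop=True),
        )

    def test_cv_is_scale_invariant_and_area_scales(self):
        sums = [90, 100, 110, 100]
        rows = [r for rep, s in enumerate(sums, 1) for r in rep_rows("S1", rep, "AAAAK", [s])]
        base = quantify_peptides(table(rows))
        scaled_rows = [(s, r, p, m, t, a * 7.5) for s, r, p, m, t, a in rows]
        scaled = quantify_peptides(table(scaled_rows))
        assert scaled.loc[0, "cv"] == pytest.approx(base.loc[0, "cv"])
        assert scaled.loc[0, "summed_area"] == pytest.approx(7.5 * base.loc[0, "summed_area"])


def quants(rows):
    df = pd.DataFrame(
        rows, columns=["sample_id", "peptide_sequence", "summed_area"]
    )
    df["cv"] = 0.0
    df["n_replicates"] = 4
    df["detected"] = df["summed_area"] > 0
    return df


class TestClassSummaries:
    def test_mean_and_net_over_member_peptides(self):
        q = quants([("S1", "AAAAK", 10.0), ("S1", "CCCCK", 30.0)])
        s = summarise_classes(q, {"AAAAK": "gamma-hordein", "CCCCK": "gamma-hordein"})
        row = s.iloc[0]
        assert row["net_area"] == 40 and row["mean_area"] == 20

    def test_alp_contributes_to_its_class_but_not_net_hordein(self):
        q = quants([("S1", "AAAAK", 10.0), ("S1", "QQQQQGQSFVQPQQQVPVEITR", 99.0)])
        s = summarise_classes(
            q, {"AAAAK": "B-hordein", "QQQQQGQSFVQPQQQVPVEITR": "ALP"}
        )
        assert set(s["protein_class"]) == {"ALP", "B-hordein"}
        assert net_hordein(s)["S1"] == 10.0

    def test_net_hordein_is_sum_of_the_four_hordein_classes(self):
        rows = [
            ("S1", "B1K", 1.0), ("S1", "C1L", 2.0), ("S1", "D1K", 4.0),
            ("S1", "G1K", 8.0), ("S1", "A1K", 100.0),
        ]
        cmap = {"B1K": "B-hordein", "C1L": "C-hordein", "D1K": "D-hordein",
                "G1K": "gamma-hordein", "A1K": "ALP"}
        s = summarise_classes(quants(rows), cmap)
        per_class = s.set_index("protein_class")["net_area"]
        assert net_hordein(s)["S1"] == per_class.drop("ALP").sum() == 15.0

    def test_unmapped_peptides_warned_and_listed(self, caplog):
        q = quants([("S1", "AAAAK", 10.0), ("S1", "ZZZZK", 5.0)])
        with caplog.at_level("WARNING"):
            s = summarise_classes(q, {"AAAAK": "B-hordein"})
        assert s.attrs["unmapped_peptides"] == ["ZZZZK"]
        assert "ZZZZK" in caplog.text

    def test_sample_without_hordein_signal_reports_zero(self):
        q = quants([("S1", "AAAAK", 10.0), ("S2", "A1K", 3.0)])
        s = summarise_classes(quants(
            [("S1", "AAAAK", 10.0), ("S2", "A1K", 3.0)]
        ), {"AAAAK": "B-hordein", "A1K": "ALP"})
        assert net_hordein(s)["S2"] == 0.0


class TestHeatmapAndWheatPanel:
    def test_undetected_cells_are_missing_markers(self):
        q = quants([("S1", "AAAAK", 10.0), ("S1", "CCCCK", 5.0), ("S2", "AAAAK", 3.0)])
        q = pd.concat(
            [q, quants([("S2", "CCCCK", 0.0)])], ignore_index=True
        )
        matrix, ann = heatmap_matrix(q, {"AAAAK": {"r5": False, "immunogenic": False}})
        assert matrix.shape == (2, 2)
        assert np.isnan(matrix.loc["S2", "CCCCK"])
        assert list(ann.index) == ["AAAAK", "CCCCK"]

    def test_matrix_row_order_is_stable(self):
        rows = [("S2", "CCCCK", 5.0), ("S1", "AAAAK", 10.0)]
        m1, _ = heatmap_matrix(quants(rows))
        m2, _ = heatmap_matrix(quants(list(reversed(rows))))
        pd.testing.assert_frame_equal(m1, m2)

    def test_single_marker_detection_flags_contamination(self):
        q = quants([("S1", "DVSPGCRPITVSPGTR", 4.0), ("S2", "AAAAK", 9.0)])
        panel = wheat_panel(q).set_index("sample_id")
        assert panel.loc["S1", "markers_detected"] == 1
        assert bool(panel.loc["S1", "contaminated"])
        assert not bool(panel.loc["S2", "contaminated"])

    def test_full_marker_panel_counted(self):
        markers = default_wheat_markers()
        assert "DVSPGCRPITVSPGTR" in markers
        q = quants([("S1", m, 1.0) for m in markers])
        panel = wheat_panel(q).set_index("sample_id")
        assert panel.loc["S1", "markers_detected"] == len(markers)


class TestElisaConcordance:
    def test_survey_table_group_means_and_percentage(self):
        report = elisa_concordance(default_elisa_table())
        # LG1-LG9 mean 53.9/9 = 5.99 mg/kg, 4% of the highest control
        assert report["group_means_raw"]["low_gluten"] == pytest.approx(53.9 / 9)
        assert report["low_gluten_vs_max_control_percent"] == 4

    def test_identical_rankings_give_rho_one_and_no_mismatches(self):
        elisa = pd.DataFrame(
            {"sample_id": ["a", "b", "c", "d"], "gluten_mg_per_kg": [1.0, 2, 3, 4]}
        )
        net = pd.Series([10.0, 20, 30, 40], index=["a", "b", "c", "d"])
        report = elisa_concordance(elisa, net, rank_margin=0)
        assert report["spearman_rho"] == pytest.approx(1.0)
        assert report["mismatch_table"].empty

    def test_rank_discordant_sample_is_listed(self):
        elisa = pd.DataFrame(
            {"sample_id": list("abcde"), "gluten_mg_per_kg": [1.0, 2, 3, 4, 0.1]}
        )
        net = pd.Series([1.0, 2, 3, 4, 100.0], index=list("abcde"))
        report = elisa_concordance(elisa, net, rank_margin=2)
        assert list(report["mismatch_table"]["sample_id"]) == ["e"]

    def test_fewer_than_three_pairs_omits_correlation(self, caplog):
        elisa = pd.DataFrame({"sample_id": ["a", "b"], "gluten_mg_per_kg": [1.0, 2]})
        net = pd.Series([5.0, 1.0], index=["a", "b"])
        with caplog.at_level("WARNING"):
            report = elisa_concordance(elisa, net)
        assert report["spearman_rho"] is None
        assert "omitted" in caplog.text
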