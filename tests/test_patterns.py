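"""Documentation-pattern matrices, note yield, correlation, co-occurrence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oudnotes import (
    annotation_table,
    frequency_matrix,
    note_yield,
    pair_correlation,
    patient_cooccurrence,
    simulate,
)
from oudnotes.corpus import TABLE_COLUMNS
from oudnotes.simulate import SimConfig


def make_table(rows):
    """rows: (patient_id, note_type, setting, position, note_id, sentence_id, class)"""
    return pd.DataFrame(
        [
            (p, "OUD-DX", "oud_diagnosis", "e1", pos, s, nt, n, sid, c, "")
            for p, nt, s, pos, n, sid, c in rows
        ],
        columns=TABLE_COLUMNS,
    )


class TestFrequencyMatrix:
    def test_empty_table_zero_filled_closed_columns(self):
        fm = frequency_matrix(pd.DataFrame(columns=TABLE_COLUMNS), "setting")
        assert list(fm.counts.columns) == ["ED", "ED_to_IPT", "OPT", "IPT"]
        assert fm.grand_total == 0

    def test_single_annotation_single_cell(self):
        t = make_table([("p1", "progress", "OPT", "index", "n1", "s1", "A")])
        fm = frequency_matrix(t, "note_type")
        assert fm.counts.loc["A", "progress"] == 1
        assert fm.grand_total == 1

    def test_class_confined_to_index_position(self):
        rows = [("p1", "progress", "OPT", "index", "n1", f"s{i}", "B") for i in range(4)]
        rows += [("p1", "progress", "OPT", "historic", "n2", "s1", "A")]
        fm = frequency_matrix(make_table(rows), "position")
        b = fm.counts.loc["B"]
        assert b["index"] == b.sum() == 4

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            frequency_matrix(pd.DataFrame(columns=TABLE_COLUMNS), "weekday")

    def test_axes_share_grand_total(self, ref_corpus):
        t = annotation_table(ref_corpus)
        totals = {
            axis: frequency_matrix(t, axis).grand_total
            for axis in ("note_type", "setting", "position")
        }
        assert len(set(totals.values())) == 1
        assert totals["note_type"] == len(t)  # class events, not sentences

    def test_margins_consistent(self, ref_corpus):
        fm = frequency_matrix(annotation_table(ref_corpus), "note_type")
        assert fm.row_totals.sum() == fm.col_totals.sum() == fm.grand_total


class TestNoteYield:
    def test_reference_progress_note_mean(self, ref_note_corpus):
        ny = note_yield(ref_note_corpus).set_index("note_type")
        prog = ny.loc["progress"]
        assert prog["n_notes"] == 92 and prog["n_annotated_notes"] == 62
        assert prog["n_sentences_annotated"] == 574
        assert round(prog["mean_sentences"], 1) == 9.3

    def test_reference_hp_annotated_share(self, ref_note_corpus):
        ny = note_yield(ref_note_corpus).set_index("note_type")
        assert round(ny.loc["h_and_p", "pct_annotated"]) == 90

    def test_totals_reconcile(self, ref_note_corpus):
        ny = note_yield(ref_note_corpus)
        assert ny["n_notes"].sum() == 320
        assert ny["n_annotated_notes"].sum() == 186
        assert ny["n_sentences_annotated"].sum() == 1436
        assert (ny["n_annotated_notes"] <= ny["n_notes"]).all()

    def test_absent_note_type_has_undefined_mean(self, ref_corpus):
        # the group fixture contains only progress notes
        ny = note_yield(ref_corpus).set_index("note_type")
        assert ny.loc["lactation", "n_notes"] == 0
        assert np.isnan(ny.loc["lactation", "mean_sentences"])

    def test_setting_counts_sum_to_annotated_notes(self, ref_note_corpus):
        ny = note_yield(ref_note_corpus)
        setting_cols = [c for c in ny.columns if c.startswith("n_annotated_") and c != "n_annotated_notes"]
        assert (ny[setting_cols].sum(axis=1) == ny["n_annotated_notes"]).all()


class TestPairCorrelation:
    def toy(self):
        # 3 classes x 4 note types; v2 = 2*v1 (collinear), v3 distinct
        return pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [5, 1, 0, 2]],
            index=["a", "b", "c"],
            columns=["t1", "t2", "t3", "t4"],
        )

    def test_diagonal_and_collinearity(self):
        pm = pair_correlation(self.toy())
        assert pm.values.loc["a", "a"] == 1.0
        assert pm.values.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_hand_computed_oracle(self):
        pm = pair_correlation(self.toy())
        expected = np.corrcoef(self.toy().to_numpy())  # independent closed form
        got = pm.values.to_numpy()
        assert np.allclose(got, expected)

    def test_spearman_ranks(self):
        pm = pair_correlation(self.toy(), method="spearman")
        assert pm.values.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_row_flagged_nan(self):
        m = self.toy()
        m.loc["z"] = [3, 3, 3, 3]
        pm = pair_correlation(m)
        assert np.isnan(pm.values.loc["z", "a"]) and np.isnan(pm.values.loc["a", "z"])
        assert np.isnan(pm.values.loc["z", "z"])

    def test_symmetric_and_column_order_invariant(self):
        m = self.toy()
        pm1 = pair_correlation(m).values
        pm2 = pair_correlation(m[["t3", "t1", "t4", "t2"]]).values
        assert np.allclose(pm1, pm1.T, equal_nan=True)
        assert np.allclose(pm1, pm2, equal_nan=True)

    def test_fewer_than_two_columns_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            pair_correlation(self.toy()[["t1"]])


class TestPatientCooccurrence:
    def test_single_patient_two_classes(self):
        t = make_table(
            [
                ("p1", "progress", "OPT", "index", "n1", "s1", "A"),
                ("p1", "progress", "OPT", "index", "n1", "s2", "B"),
            ]
        )
        pm = patient_cooccurrence(t).values
        assert pm.loc["A", "B"] == 1
        assert pm.loc["A", "A"] == pm.loc["B", "B"] == 1

    def test_matches_brute_force_on_simulated_corpus(self, crosswalk):
        cfg = SimConfig(group_sizes={"OUD-DX": 20})
        corpus, _ = simulate(cfg, crosswalk, seed=9)
        t = annotation_table(corpus)
        pm = patient_cooccurrence(t).values
        # brute force: double loop over patients and class pairs
        by_patient = t.groupby("patient_id")["class_name"].agg(set)
        for ci, cj in itertools.product(pm.index, repeat=2):
            expected = sum(1 for s in by_patient if ci in s and cj in s)
            assert pm.loc[ci, cj] == expected

    def test_cooccurrence_bounded_by_diagonal(self, crosswalk):
        cfg = SimConfig(group_sizes={"OUD-TX": 20})
        corpus, _ = simulate(cfg, crosswalk, seed=10)
        pm = patient_cooccurrence(annotation_table(corpus)).values
        diag = np.diag(pm.to_numpy())
        assert (pm.to_numpy() <= np.minimum.outer(diag, diag)).all()
        assert np.allclose(pm.to_numpy(), pm.to_numpy().T)
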