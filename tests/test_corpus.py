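"""Corpus data model, JSONL round trips, and the flat annotation table."""

import json

import pytest

from oudnotes import (
    Annotation,
    Corpus,
    CorpusValidationError,
    Encounter,
    Group,
    IndexReason,
    Note,
    NoteType,
    Patient,
    Position,
    Sentence,
    Setting,
    annotation_table,
    read_corpus,
    write_corpus,
)
from oudnotes.corpus import table_counts
from oudnotes.reference import GROUP_TABLE


def tiny_corpus() -> Corpus:
    c = Corpus()
    c.patients["p1"] = Patient(
        patient_id="p1", group=Group.OUD_TX, index_reason=IndexReason.oud_diagnosis
    )
    c.encounters["e1"] = Encounter(
        encounter_id="e1", patient_id="p1", position=Position.index, setting=Setting.ED
    )
    c.notes.append(
        Note(
            note_id="n1",
            encounter_id="e1",
            note_type=NoteType.ed,
            sentences=(
                Sentence(
                    sentence_id="s1",
                    text="placeholder",
                    annotations=(
                        Annotation(annotator_id="gold", class_name="opioid craving"),
                        Annotation(
                            annotator_id="gold",
                            class_name="opioid withdrawal",
                            attributes={"temporality": "current"},
                        ),
                    ),
                ),
                Sentence(
                    sentence_id="s2",
                    annotations=(
                        Annotation(annotator_id="A1", class_name="daily tobacco use"),
                    ),
                ),
            ),
        )
    )
    return c.validate()


class TestRoundTrip:
    def test_empty_file_gives_empty_corpus(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("", encoding="utf-8")
        c = read_corpus(p)
        assert c.counts()["notes"] == 0

    def test_empty_corpus_writes_zero_note_lines(self, tmp_path):
        p = tmp_path / "out.jsonl"
        write_corpus(Corpus(), p)
        assert p.read_text() == ""

    def test_single_note_is_single_line(self, tmp_path):
        p = tmp_path / "one.jsonl"
        write_corpus(tiny_corpus(), p)
        assert len(p.read_text().strip().splitlines()) == 1

    def test_round_trip_equality(self, tmp_path, ref_corpus):
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus(ref_corpus, p1)
        reread = read_corpus(p1)
        assert reread.patients == ref_corpus.patients
        assert reread.encounters == ref_corpus.encounters
        write_corpus(reread, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestValidation:
    def test_unknown_setting_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        write_corpus(tiny_corpus(), p)
        line = json.loads(p.read_text())
        line["encounter"]["setting"] = "ICU"
        p.write_text(json.dumps(line) + "\n", encoding="utf-8")
        with pytest.raises(CorpusValidationError, match="line 1"):
            read_corpus(p)

    def test_duplicate_note_id_rejected(self, tmp_path):
        p = tmp_path / "dup.jsonl"
        write_corpus(tiny_corpus(), p)
        p.write_text(p.read_text() * 2, encoding="utf-8")
        with pytest.raises(CorpusValidationError, match="duplicate note ids"):
            read_corpus(p)

    def test_group_index_reason_consistency(self):
        with pytest.raises(CorpusValidationError, match="index_reason"):
            c = Corpus()
            c.patients["p"] = Patient(
                patient_id="p", group=Group.CONTROL, index_reason=IndexReason.oud_diagnosis
            )
            c.validate()

    def test_encounters_require_an_index_position(self):
        c = Corpus()
        c.patients["p"] = Patient(
            patient_id="p", group=Group.OUD_DX, index_reason=IndexReason.oud_diagnosis
        )
        c.encounters["e"] = Encounter(
            encounter_id="e", patient_id="p", position=Position.historic, setting=Setting.ED
        )
        with pytest.raises(CorpusValidationError, match="index position"):
            c.validate()

    def test_broken_encounter_reference(self):
        c = tiny_corpus()
        c.notes.append(Note(note_id="n2", encounter_id="missing", note_type=NoteType.ed))
        with pytest.raises(CorpusValidationError, match="unknown encounter"):
            c.validate()


class TestAnnotationTable:
    def test_one_row_per_annotation(self):
        t = annotation_table(tiny_corpus(), "gold")
        assert len(t) == 2
        assert set(t["class_name"]) == {"opioid craving", "opioid withdrawal"}

    def test_multilabel_sentence_shares_sentence_id(self):
        t = annotation_table(tiny_corpus(), "gold")
        assert t["sentence_id"].nunique() == 1

    def test_unknown_annotator_raises(self):
        with pytest.raises(KeyError, match="A9"):
            annotation_table(tiny_corpus(), "A9")

    def test_gold_layer_always_allowed(self):
        c = Corpus()
        assert annotation_table(c, "gold").empty

    def test_union_of_layers(self):
        t = annotation_table(tiny_corpus(), ["gold", "A1"])
        assert len(t) == 3

    def test_reference_fixture_totals(self, ref_corpus):
        counts = table_counts(annotation_table(ref_corpus, "gold"))
        assert counts["annotated_sentences"] == 1436
        assert counts["annotated_notes"] == 186
        assert counts["annotated_patients"] == 82

    def test_per_group_sentence_counts_match_encoding(self, ref_corpus):
        t = annotation_table(ref_corpus, "gold")
        per_group = (
            t[["group", "note_id", "sentence_id"]].drop_duplicates().groupby("group").size()
        )
        for group, (_, _, _, _, n_sent) in GROUP_TABLE.items():
            assert per_group[group] == n_sent
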