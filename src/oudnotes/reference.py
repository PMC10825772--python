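"""Reference fixtures encoding the development study's summary tables.

The chart-review study this framework was developed on published only
summary counts (its clinical notes cannot be shared).  This module encodes
those counts — per-group patient/note/sentence totals, per-group severity
category counts split by index-encounter reason, and the per-note-type
yield table — and builds small synthetic corpora whose annotation-layer
summaries reproduce them exactly.  The fixtures are the ground against
which the scoring and evaluation modules are checked: every published
quantity that is arithmetically determined by these counts (PPVs, severity
means, yield statistics) must be recomputable from the fixture corpora.

Fixture sentences carry no text; the class lists assigned to each patient
are chosen from the default crosswalk so the patient's criterion count
lands exactly in the published severity category (severe patients score 7
or 8, within the published score distribution for their stratum).
"""

from __future__ import annotations

import itertools

import pandas as pd

from .corpus import (
    GOLD_ANNOTATOR,
    Annotation,
    Corpus,
    Encounter,
    Group,
    IndexReason,
    Note,
    NoteType,
    Patient,
    Position,
    Sentence,
    Setting,
)
from .schema import Crosswalk, default_crosswalk

__all__ = [
    "GROUP_TABLE",
    "SEVERITY_JOINT",
    "UNANNOTATED",
    "NOTE_TYPE_TABLE",
    "GROUP_SAMPLE_SIZE",
    "reference_corpus",
    "reference_note_corpus",
]

#: Designed sample size per study group.
GROUP_SAMPLE_SIZE = 20

#: Per-group counts among patients whose notes yielded annotations:
#: (n_annotated_patients, n_index_oud_diagnosis, n_index_opioid_order,
#:  n_notes_with_annotations, n_annotated_sentences).
GROUP_TABLE: dict[str, tuple[int, int, int, int, int]] = {
    "CP-RX": (16, 8, 8, 29, 170),
    "CP-nonRX": (18, 14, 4, 32, 277),
    "OUD-DX": (19, 19, 0, 50, 363),
    "OUD-TX": (20, 20, 0, 61, 602),
    "Control": (9, 0, 9, 14, 24),
}

#: Joint (index_reason, severity category) patient counts per group.  The
#: study printed the two margins (per-group categories; per-reason
#: categories over noncontrol patients); this joint satisfies both.  Among
#: order-indexed annotated patients all are "none" except one severe
#: CP-nonRX patient.
SEVERITY_JOINT: dict[str, list[tuple[str, str, int]]] = {
    "CP-RX": [
        ("oud_diagnosis", "moderate", 1),
        ("oud_diagnosis", "severe", 7),
        ("opioid_order", "none", 8),
    ],
    "CP-nonRX": [
        ("oud_diagnosis", "none", 4),
        ("oud_diagnosis", "moderate", 1),
        ("oud_diagnosis", "severe", 9),
        ("opioid_order", "none", 3),
        ("opioid_order", "severe", 1),
    ],
    "OUD-DX": [
        ("oud_diagnosis", "none", 3),
        ("oud_diagnosis", "mild", 1),
        ("oud_diagnosis", "moderate", 1),
        ("oud_diagnosis", "severe", 14),
    ],
    "OUD-TX": [
        ("oud_diagnosis", "none", 1),
        ("oud_diagnosis", "mild", 1),
        ("oud_diagnosis", "moderate", 1),
        ("oud_diagnosis", "severe", 17),
    ],
    "Control": [("opioid_order", "none", 9)],
}

#: Sampled patients whose notes yielded no annotations: group -> list of
#: index reasons (16 of the 18 were order-indexed; 11 were controls).
UNANNOTATED: dict[str, list[str]] = {
    "CP-RX": ["opioid_order"] * 4,
    "CP-nonRX": ["opioid_order", "oud_diagnosis"],
    "OUD-DX": ["oud_diagnosis"],
    "OUD-TX": [],
    "Control": ["opioid_order"] * 11,
}

#: Per-note-type yield: (n_notes, n_annotated_notes,
#: {setting: annotated-note count}, n_annotated_sentences).
NOTE_TYPE_TABLE: dict[str, tuple[int, int, dict[str, int], int]] = {
    "progress": (92, 62, {"ED": 1, "ED_to_IPT": 7, "OPT": 3, "IPT": 51}, 574),
    "h_and_p": (30, 27, {"ED": 8, "ED_to_IPT": 13, "OPT": 6, "IPT": 0}, 196),
    "ed": (32, 25, {"ED": 21, "ED_to_IPT": 4, "OPT": 0, "IPT": 0}, 237),
    "ed_provider": (28, 23, {"ED": 18, "ED_to_IPT": 5, "OPT": 0, "IPT": 0}, 177),
    "discharge_summary": (26, 23, {"ED": 5, "ED_to_IPT": 10, "OPT": 8, "IPT": 0}, 172),
    "ed_triage": (26, 9, {"ED": 9, "ED_to_IPT": 0, "OPT": 0, "IPT": 0}, 22),
    "ancillary_progress": (30, 9, {"ED": 2, "ED_to_IPT": 4, "OPT": 3, "IPT": 0}, 19),
    "communication": (12, 3, {"ED": 0, "ED_to_IPT": 2, "OPT": 1, "IPT": 0}, 5),
    "outpatient_clinic": (4, 2, {"ED": 0, "ED_to_IPT": 0, "OPT": 0, "IPT": 2}, 26),
    "ed_support_staff": (38, 2, {"ED": 1, "ED_to_IPT": 1, "OPT": 0, "IPT": 0}, 7),
    "lactation": (2, 1, {"ED": 0, "ED_to_IPT": 0, "OPT": 1, "IPT": 0}, 1),
}

# class lists realising each severity category with the default crosswalk;
# the seven base classes endorse seven distinct criteria, the eighth an
# eighth criterion.
_SEVERE_BASE = [
    "opioid craving",             # criterion 4
    "opioid withdrawal",          # criterion 11
    "opioid tolerance",           # criterion 10
    "drug seeking",               # criterion 3
    "intoxication",               # criterion 8
    "opioid misuse-illicit",      # criterion 1
    "unsuccessful attempts to cut down",  # criterion 2
]
_EIGHTH = "social consequences"   # criterion 6
_NONE_CLASS = "history of substance misuse"  # non-scoring
#: number of severe patients scored 8 rather than 7 (fits the published
#: mean scores: 5.1 noncontrol, 6.0 diagnosis-indexed, 0.6 order-indexed)
_N_SCORE_EIGHT = 14


def _classes_for(category: str, moderate_score: int, severe_score: int, treated: bool) -> list[str]:
    if category == "none":
        return [_NONE_CLASS]
    if category == "mild":
        return _SEVERE_BASE[:2]
    if category == "moderate":
        return _SEVERE_BASE[:moderate_score]
    classes = list(_SEVERE_BASE) + ([_EIGHTH] if severe_score == 8 else [])
    if treated:
        classes.append("OUD treatment")
    return classes


def _patient_specs() -> dict[str, list[tuple[str, list[str]]]]:
    """Per group: list of (index_reason, class list) for annotated patients."""
    specs: dict[str, list[tuple[str, list[str]]]] = {g: [] for g in GROUP_TABLE}
    eights = itertools.count()
    moderate_scores = itertools.cycle([4, 5])
    for group in ("CP-RX", "CP-nonRX", "OUD-DX", "OUD-TX"):
        for reason, category, n in SEVERITY_JOINT[group]:
            for _ in range(n):
                if category == "severe" and reason == "oud_diagnosis":
                    severe_score = 8 if next(eights) < _N_SCORE_EIGHT else 7
                else:
                    severe_score = 7
                specs[group].append(
                    (
                        reason,
                        _classes_for(
                            category,
                            next(moderate_scores) if category == "moderate" else 0,
                            severe_score,
                            treated=(group == "OUD-TX" and category == "severe"),
                        ),
                    )
                )
    for reason, category, n in SEVERITY_JOINT["Control"]:
        specs["Control"].extend((reason, [_NONE_CLASS]) for _ in range(n))
    return specs


def reference_corpus(crosswalk: Crosswalk | None = None) -> Corpus:
    """Fixture corpus reproducing the group and severity summary tables.

    100 sampled patients (82 with annotations), with per-group annotated
    note and sentence totals matching :data:`GROUP_TABLE` and severity
    categories matching :data:`SEVERITY_JOINT`.  Chart structure is
    deliberately flat: progress notes at index outpatient encounters.
    Sentences beyond a patient's distinct class list repeat their first
    class, which leaves the score unchanged (set semantics).
    """
    crosswalk = crosswalk or default_crosswalk()
    specs = _patient_specs()
    corpus = Corpus(provenance={"source": "reference-tables-fixture"})

    for group, patients in specs.items():
        n_annot, _, _, n_notes, n_sentences = GROUP_TABLE[group]
        assert len(patients) == n_annot
        # sentence allocation: one per distinct class, extras round-robin
        needed = [len(classes) for _, classes in patients]
        extra = n_sentences - sum(needed)
        assert extra >= 0, group
        totals = list(needed)
        for k in range(extra):
            totals[k % n_annot] += 1
        # note allocation: one each, extras round-robin where sentences allow
        note_counts = [1] * n_annot
        remaining = n_notes - n_annot
        for k in itertools.cycle(range(n_annot)):
            if remaining == 0:
                break
            if totals[k] > note_counts[k]:
                note_counts[k] += 1
                remaining -= 1

        for i, (reason, classes) in enumerate(patients):
            pid = f"{group}-P{i:02d}"
            corpus.patients[pid] = Patient(
                patient_id=pid, group=Group(group), index_reason=IndexReason(reason)
            )
            eid = f"{pid}-e0"
            corpus.encounters[eid] = Encounter(
                encounter_id=eid,
                patient_id=pid,
                position=Position.index,
                setting=Setting.OPT,
            )
            # spread sentences over notes: each note >= 1, remainder on note 0
            sentence_classes = classes + [classes[0]] * (totals[i] - len(classes))
            per_note = [1] * note_counts[i]
            per_note[0] += totals[i] - note_counts[i]
            cursor = 0
            for m, cnt in enumerate(per_note):
                sentences = []
                for s in range(cnt):
                    cls = sentence_classes[cursor]
                    cursor += 1
                    attrs = (
                        {"temporality": "current"}
                        if "temporality" in crosswalk[cls].attributes
                        else {}
                    )
                    sentences.append(
                        Sentence(
                            sentence_id=f"{pid}-n{m}-s{s}",
                            annotations=(
                                Annotation(
                                    annotator_id=GOLD_ANNOTATOR,
                                    class_name=cls,
                                    attributes=attrs,
                                ),
                            ),
                        )
                    )
                corpus.notes.append(
                    Note(
                        note_id=f"{pid}-n{m}",
                        encounter_id=eid,
                        note_type=NoteType.progress,
                        sentences=tuple(sentences),
                    )
                )

        # sampled patients whose notes yielded nothing
        for j, reason in enumerate(UNANNOTATED[group]):
            pid = f"{group}-U{j:02d}"
            corpus.patients[pid] = Patient(
                patient_id=pid, group=Group(group), index_reason=IndexReason(reason)
            )
            eid = f"{pid}-e0"
            corpus.encounters[eid] = Encounter(
                encounter_id=eid,
                patient_id=pid,
                position=Position.index,
                setting=Setting.OPT,
            )
            corpus.notes.append(
                Note(
                    note_id=f"{pid}-n0",
                    encounter_id=eid,
                    note_type=NoteType.progress,
                    sentences=(Sentence(sentence_id=f"{pid}-n0-s0"),),
                )
            )
    return corpus.validate()


def reference_note_corpus() -> Corpus:
    """Fixture corpus reproducing the per-note-type yield table.

    320 notes of the 11 types with the published annotated-note counts,
    per-setting breakdowns of annotated notes, and annotated-sentence
    totals (sentences spread as evenly as possible, so the per-type mean is
    exactly the published total / annotated-note count).
    """
    corpus = Corpus(provenance={"source": "reference-noteyield-fixture"})
    for nt, (n_notes, n_annot, settings, n_sentences) in NOTE_TYPE_TABLE.items():
        pid = f"NY-{nt}"
        corpus.patients[pid] = Patient(
            patient_id=pid, group=Group.OUD_DX, index_reason=IndexReason.oud_diagnosis
        )
        used_settings = [s for s, c in settings.items() if c > 0] or ["OPT"]
        enc_of: dict[str, str] = {}
        for s in ("ED", "ED_to_IPT", "OPT", "IPT"):
            if s in used_settings:
                eid = f"{pid}-{s}"
                corpus.encounters[eid] = Encounter(
                    encounter_id=eid,
                    patient_id=pid,
                    position=Position.index,
                    setting=Setting(s),
                )
                enc_of[s] = eid
        # annotated notes with near-even sentence counts
        base, rem = divmod(n_sentences, n_annot)
        sent_counts = [base + 1] * rem + [base] * (n_annot - rem)
        note_settings = [s for s, c in settings.items() for _ in range(c)]
        assert len(note_settings) == n_annot
        for m, (cnt, s) in enumerate(zip(sent_counts, note_settings)):
            sentences = tuple(
                Sentence(
                    sentence_id=f"{pid}-a{m}-s{k}",
                    annotations=(
                        Annotation(annotator_id=GOLD_ANNOTATOR, class_name=_NONE_CLASS),
                    ),
                )
                for k in range(cnt)
            )
            corpus.notes.append(
                Note(
                    note_id=f"{pid}-a{m}",
                    encounter_id=enc_of[s],
                    note_type=NoteType(nt),
                    sentences=sentences,
                )
            )
        # notes that yielded nothing
        fallback = max(used_settings, key=lambda s: settings.get(s, 0))
        for m in range(n_notes - n_annot):
            corpus.notes.append(
                Note(
                    note_id=f"{pid}-u{m}",
                    encounter_id=enc_of[fallback],
                    note_type=NoteType(nt),
                    sentences=(Sentence(sentence_id=f"{pid}-u{m}-s0"),),
                )
            )
    return corpus.validate()


def group_sample_sizes() -> dict[str, int]:
    """Designed per-stratum sample sizes (20 per group)."""
    return {g: GROUP_SAMPLE_SIZE for g in GROUP_TABLE}


def reference_summary() -> pd.DataFrame:
    """The encoded group table as a DataFrame (one row per group)."""
    return pd.DataFrame(
        [
            {
                "group": g,
                "n_sampled": GROUP_SAMPLE_SIZE,
                "n_annotated": v[0],
                "n_index_oud_diagnosis": v[1],
                "n_index_opioid_order": v[2],
                "n_notes_annotated": v[3],
                "n_sentences_annotated": v[4],
            }
            for g, v in GROUP_TABLE.items()
        ]
    )
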