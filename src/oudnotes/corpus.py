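"""Hierarchical annotated-corpus data model and JSONL I/O.

The unit of storage is the clinical note.  Notes belong to encounters
(positioned *historic*, *index*, or *new* relative to the patient's index
date and occurring in one of four settings), encounters belong to patients
(drawn from one of five study groups), and notes contain ordered sentences,
each carrying zero or more class annotations per annotator layer.  The
adjudicated consensus layer uses the reserved annotator id ``"gold"``.

On disk a corpus is JSONL: one JSON object per note, UTF-8, with the
patient and encounter headers repeated on every line so each line is
self-contained.  Sentence text is optional throughout — the framework
operates on labels, which keeps fixtures free of clinical language.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

__all__ = [
    "Group",
    "IndexReason",
    "Position",
    "Setting",
    "NoteType",
    "Annotation",
    "Sentence",
    "Note",
    "Encounter",
    "Patient",
    "Corpus",
    "CorpusValidationError",
    "GOLD_ANNOTATOR",
    "read_corpus",
    "write_corpus",
    "annotation_table",
    "TABLE_COLUMNS",
]

#: Reserved annotator id of the adjudicated consensus layer.
GOLD_ANNOTATOR = "gold"


class CorpusValidationError(ValueError):
    """A corpus file or in-memory corpus violates a structural invariant."""


class Group(str, enum.Enum):
    """Study group a patient was sampled from."""

    CP_RX = "CP-RX"            # chronic pain, OUD began with a prescription
    CP_NONRX = "CP-nonRX"      # chronic pain, OUD did not begin with a prescription
    OUD_DX = "OUD-DX"          # OUD diagnosis, no medication treatment order
    OUD_TX = "OUD-TX"          # OUD diagnosis with medication treatment order
    CONTROL = "Control"        # single opioid analgesic order, no OUD evidence


class IndexReason(str, enum.Enum):
    """Why the patient's index encounter was selected."""

    oud_diagnosis = "oud_diagnosis"
    opioid_order = "opioid_order"


class Position(str, enum.Enum):
    """Encounter position relative to the index date."""

    historic = "historic"
    index = "index"
    new = "new"


class Setting(str, enum.Enum):
    """Encounter setting."""

    ED = "ED"
    ED_to_IPT = "ED_to_IPT"
    OPT = "OPT"
    IPT = "IPT"


class NoteType(str, enum.Enum):
    """The 11 clinical note types in the corpus design."""

    progress = "progress"
    ancillary_progress = "ancillary_progress"
    h_and_p = "h_and_p"
    discharge_summary = "discharge_summary"
    ed = "ed"
    ed_provider = "ed_provider"
    ed_triage = "ed_triage"
    ed_support_staff = "ed_support_staff"
    communication = "communication"
    outpatient_clinic = "outpatient_clinic"
    lactation = "lactation"


class Annotation(BaseModel):
    """One class label applied to one sentence by one annotator."""

    model_config = ConfigDict(frozen=True)

    annotator_id: str
    class_name: str
    attributes: dict[str, str] = {}


class Sentence(BaseModel):
    sentence_id: str
    text: Optional[str] = None
    annotations: tuple[Annotation, ...] = ()


class Note(BaseModel):
    note_id: str
    encounter_id: str
    note_type: NoteType
    sentences: tuple[Sentence, ...] = ()


class Encounter(BaseModel):
    model_config = ConfigDict(frozen=True)

    encounter_id: str
    patient_id: str
    position: Position
    setting: Setting
    date: Optional[str] = None


class Patient(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    group: Group
    index_reason: IndexReason
    sex: Optional[str] = None
    age_stratum: Optional[str] = None


# group/index_reason combinations fixed by the study design
_GROUP_REASONS: dict[Group, frozenset[IndexReason]] = {
    Group.OUD_DX: frozenset({IndexReason.oud_diagnosis}),
    Group.OUD_TX: frozenset({IndexReason.oud_diagnosis}),
    Group.CONTROL: frozenset({IndexReason.opioid_order}),
    Group.CP_RX: frozenset({IndexReason.oud_diagnosis, IndexReason.opioid_order}),
    Group.CP_NONRX: frozenset({IndexReason.oud_diagnosis, IndexReason.opioid_order}),
}


@dataclass
class Corpus:
    """An annotated note corpus with referential integrity guarantees."""

    patients: dict[str, Patient] = field(default_factory=dict)
    encounters: dict[str, Encounter] = field(default_factory=dict)
    notes: list[Note] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    # -- validation --------------------------------------------------------

    def validate(self) -> "Corpus":
        note_ids = [n.note_id for n in self.notes]
        dup = sorted({i for i, c in Counter(note_ids).items() if c > 1})
        if dup:
            raise CorpusValidationError(f"duplicate note ids: {dup}")
        for pid, patient in self.patients.items():
            if pid != patient.patient_id:
                raise CorpusValidationError(f"patient key {pid!r} != id {patient.patient_id!r}")
            if patient.index_reason not in _GROUP_REASONS[patient.group]:
                raise CorpusValidationError(
                    f"patient {pid}: index_reason {patient.index_reason.value!r} "
                    f"inconsistent with group {patient.group.value!r}"
                )
        per_patient_positions: dict[str, set[Position]] = {}
        for eid, enc in self.encounters.items():
            if eid != enc.encounter_id:
                raise CorpusValidationError(f"encounter key {eid!r} != id {enc.encounter_id!r}")
            if enc.patient_id not in self.patients:
                raise CorpusValidationError(
                    f"encounter {eid}: unknown patient {enc.patient_id!r}"
                )
            per_patient_positions.setdefault(enc.patient_id, set()).add(enc.position)
        for pid, positions in per_patient_positions.items():
            if Position.index not in positions:
                raise CorpusValidationError(
                    f"patient {pid}: has encounters but none at the index position"
                )
        for note in self.notes:
            if note.encounter_id not in self.encounters:
                raise CorpusValidationError(
                    f"note {note.note_id}: unknown encounter {note.encounter_id!r}"
                )
            sids = [s.sentence_id for s in note.sentences]
            if len(sids) != len(set(sids)):
                raise CorpusValidationError(
                    f"note {note.note_id}: duplicate sentence ids"
                )
        return self

    # -- convenience -------------------------------------------------------

    @property
    def annotators(self) -> frozenset[str]:
        return frozenset(
            a.annotator_id for n in self.notes for s in n.sentences for a in s.annotations
        )

    def counts(self) -> dict[str, int]:
        """Corpus size summary: patients, notes, sentences, annotations."""
        return {
            "patients": len(self.patients),
            "encounters": len(self.encounters),
            "notes": len(self.notes),
            "sentences": sum(len(n.sentences) for n in self.notes),
            "annotations": sum(
                len(s.annotations) for n in self.notes for s in n.sentences
            ),
        }


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------

def _note_record(corpus: Corpus, note: Note) -> dict:
    enc = corpus.encounters[note.encounter_id]
    pat = corpus.patients[enc.patient_id]
    record: dict = {
        "patient": {
            "patient_id": pat.patient_id,
            "group": pat.group.value,
            "index_reason": pat.index_reason.value,
        },
        "encounter": {
            "encounter_id": enc.encounter_id,
            "position": enc.position.value,
            "setting": enc.setting.value,
        },
        "note": {"note_id": note.note_id, "note_type": note.note_type.value},
        "sentences": [],
    }
    if pat.sex is not None:
        record["patient"]["sex"] = pat.sex
    if pat.age_stratum is not None:
        record["patient"]["age_stratum"] = pat.age_stratum
    if enc.date is not None:
        record["encounter"]["date"] = enc.date
    for s in note.sentences:
        srec: dict = {"sentence_id": s.sentence_id}
        if s.text is not None:
            srec["text"] = s.text
        srec["annotations"] = [
            {
                "annotator_id": a.annotator_id,
                "class": a.class_name,
                **({"attributes": dict(a.attributes)} if a.attributes else {}),
            }
            for a in s.annotations
        ]
        record["sentences"].append(srec)
    return record


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL, one note per line, in canonical order."""
    corpus.validate()
    path = Path(path)
    ordered = sorted(
        corpus.notes,
        key=lambda n: (
            corpus.encounters[n.encounter_id].patient_id,
            n.encounter_id,
            n.note_id,
        ),
    )
    with path.open("w", encoding="utf-8") as fh:
        if corpus.provenance:
            fh.write(json.dumps({"provenance": corpus.provenance}, sort_keys=True) + "\n")
        for note in ordered:
            fh.write(json.dumps(_note_record(corpus, note)) + "\n")


def _parse_note_line(raw: dict, lineno: int, corpus: Corpus) -> None:
    try:
        p = raw["patient"]
        patient = Patient(
            patient_id=p["patient_id"],
            group=p["group"],
            index_reason=p["index_reason"],
            sex=p.get("sex"),
            age_stratum=p.get("age_stratum"),
        )
        e = raw["encounter"]
        encounter = Encounter(
            encounter_id=e["encounter_id"],
            patient_id=patient.patient_id,
            position=e["position"],
            setting=e["setting"],
            date=e.get("date"),
        )
        sentences = []
        for s in raw.get("sentences", []):
            anns = tuple(
                Annotation(
                    annotator_id=a["annotator_id"],
                    class_name=a["class"],
                    attributes=a.get("attributes", {}),
                )
                for a in s.get("annotations", [])
            )
            sentences.append(
                Sentence(sentence_id=s["sentence_id"], text=s.get("text"), annotations=anns)
            )
        note = Note(
            note_id=raw["note"]["note_id"],
            encounter_id=encounter.encounter_id,
            note_type=raw["note"]["note_type"],
            sentences=tuple(sentences),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise CorpusValidationError(f"line {lineno}: {exc}") from exc

    existing = corpus.patients.get(patient.patient_id)
    if existing is not None and existing != patient:
        raise CorpusValidationError(
            f"line {lineno}: patient {patient.patient_id!r} redefined inconsistently"
        )
    corpus.patients[patient.patient_id] = patient
    existing_enc = corpus.encounters.get(encounter.encounter_id)
    if existing_enc is not None and existing_enc != encounter:
        raise CorpusValidationError(
            f"line {lineno}: encounter {encounter.encounter_id!r} redefined inconsistently"
        )
    corpus.encounters[encounter.encounter_id] = encounter
    corpus.notes.append(note)


def read_corpus(path: str | Path) -> Corpus:
    """Read and validate a JSONL corpus file.

    Raises ``CorpusValidationError`` with the offending line number for
    malformed records, unknown enum values, or broken id references.
    """
    path = Path(path)
    corpus = Corpus()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(f"line {lineno}: not valid JSON: {exc}") from exc
            if "provenance" in raw and "note" not in raw:
                corpus.provenance = raw["provenance"]
                continue
            _parse_note_line(raw, lineno, corpus)
    return corpus.validate()


# ---------------------------------------------------------------------------
# Flat annotation table
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "patient_id",
    "group",
    "index_reason",
    "encounter_id",
    "position",
    "setting",
    "note_type",
    "note_id",
    "sentence_id",
    "class_name",
    "attributes",
]


def annotation_table(
    corpus: Corpus, annotator_id: str | Sequence[str] = GOLD_ANNOTATOR
) -> pd.DataFrame:
    """Flatten one annotator layer to a tidy table, one row per annotation.

    A sentence bearing *k* classes contributes *k* rows (class-frequency
    events); count distinct ``(note_id, sentence_id)`` pairs to recover the
    number of annotated sentences.  ``annotator_id`` may be a sequence of
    annotator ids, in which case rows from all requested layers are returned
    (no deduplication across annotators — deduplicate on class columns for a
    union-of-annotators analysis).

    The ``"gold"`` layer may always be requested; any other annotator must
    be present in the corpus.
    """
    wanted = {annotator_id} if isinstance(annotator_id, str) else set(annotator_id)
    present = corpus.annotators
    missing = {a for a in wanted if a != GOLD_ANNOTATOR and a not in present}
    if missing:
        raise KeyError(f"unknown annotator(s) {sorted(missing)}; corpus has {sorted(present)}")

    rows = []
    for note in corpus.notes:
        enc = corpus.encounters[note.encounter_id]
        pat = corpus.patients[enc.patient_id]
        for sentence in note.sentences:
            for ann in sentence.annotations:
                if ann.annotator_id not in wanted:
                    continue
                rows.append(
                    (
                        pat.patient_id,
                        pat.group.value,
                        pat.index_reason.value,
                        enc.encounter_id,
                        enc.position.value,
                        enc.setting.value,
                        note.note_type.value,
                        note.note_id,
                        sentence.sentence_id,
                        ann.class_name,
                        ";".join(f"{k}={v}" for k, v in sorted(ann.attributes.items())),
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def table_counts(table: pd.DataFrame) -> dict[str, int]:
    """Both counting conventions for an annotation table.

    ``class_events``: number of rows (a sentence with k classes counts k).
    ``annotated_sentences``: distinct (note_id, sentence_id) pairs.
    ``annotated_notes`` / ``annotated_patients``: distinct ids with >=1 row.
    """
    if table.empty:
        return {
            "class_events": 0,
            "annotated_sentences": 0,
            "annotated_notes": 0,
            "annotated_patients": 0,
        }
    return {
        "class_events": int(len(table)),
        "annotated_sentences": int(
            table[["note_id", "sentence_id"]].drop_duplicates().shape[0]
        ),
        "annotated_notes": int(table["note_id"].nunique()),
        "annotated_patients": int(table["patient_id"].nunique()),
    }
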