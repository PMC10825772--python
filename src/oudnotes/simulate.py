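"""Synthetic annotated-corpus generator with known ground truth.

The generator emulates the study design the framework was developed on:
five groups of patients sampled around an index encounter, three encounter
dates (historic / index / new), notes of 11 types across 4 settings, and
sentence-level class annotations.  Severity structure is driven by a latent
per-patient DSM-5 criterion set: the generator draws a criterion count from
a group-specific zero-inflated truncated Poisson, picks scoring classes
whose crosswalk image covers the drawn set exactly, adds non-scoring
background classes, and scatters the class events over annotated sentences.
Because every chosen class is emitted at least once (at zero note dropout),
scoring the simulated corpus recovers the recorded ground truth exactly —
the property the round-trip tests rely on.

Sentence counts per annotated note follow a shifted negative binomial
(1 + NB) whose mean equals the configured per-note-type mean.  Sentence
"text" is a placeholder token; no clinical language is synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

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
from .schema import Crosswalk, SeverityCategory, default_crosswalk
from .scoring import SEVERE_MIN_SCORE, categorize

__all__ = ["SimConfig", "SimConfigError", "simulate", "study_calibrated_config", "drop_notes"]


class SimConfigError(ValueError):
    """The generator configuration is inconsistent with the crosswalk."""


class CriterionCountMixture(BaseModel):
    """P(count = 0) = p_zero; otherwise 1..11 truncated Poisson(lam)."""

    model_config = ConfigDict(frozen=True)

    p_zero: float
    lam: float

    @field_validator("p_zero")
    @classmethod
    def _p_in_unit(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p_zero {v} outside [0, 1]")
        return v


def _study_defaults() -> dict:
    text = resources.files("oudnotes.data").joinpath("sim_default.yaml").read_text("utf-8")
    return yaml.safe_load(text)


class SimConfig(BaseModel):
    """Generator parameters; defaults are the study-calibrated values.

    All group-keyed dictionaries must cover every group in ``group_sizes``;
    groups absent from ``group_sizes`` are simply not generated, so a
    control-only configuration is just ``group_sizes={"Control": 20}``.
    """

    model_config = ConfigDict(frozen=True)

    group_sizes: dict[Group, int]
    p_annotatable: dict[Group, float]
    p_index_oud_diagnosis: dict[Group, float]
    criterion_count: dict[Group, CriterionCountMixture]
    p_treatment: dict[Group, float]
    noise_class_rates: dict[str, float]
    setting_mix: dict[Setting, float]
    note_type_mix: dict[Setting, dict[NoteType, float]]
    sentences_per_note: dict[NoteType, float]
    sentence_dispersion: float = 1.2
    extra_notes_rate: float = 0.2
    p_note_annotated: dict[Position, float]
    p_historic_attribute: float = 0.3
    p_second_class: float = 0.1
    note_dropout: float = 0.0
    annotator_flip_rate: float = 0.0
    seed: int = 0

    def __init__(self, **data):
        defaults = _study_defaults()
        merged = {**defaults, **data}
        super().__init__(**merged)

    @model_validator(mode="after")
    def _validate(self) -> "SimConfig":
        for name in ("p_annotatable", "p_index_oud_diagnosis", "p_treatment"):
            mapping = getattr(self, name)
            for g in self.group_sizes:
                if g not in mapping:
                    raise ValueError(f"{name} missing group {g.value!r}")
                if not 0.0 <= mapping[g] <= 1.0:
                    raise ValueError(f"{name}[{g.value}] outside [0, 1]")
        for g in self.group_sizes:
            if g not in self.criterion_count:
                raise ValueError(f"criterion_count missing group {g.value!r}")
        for probs, label in [(self.setting_mix, "setting_mix")] + [
            (m, f"note_type_mix[{s.value}]") for s, m in self.note_type_mix.items()
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{label} sums to {total}, expected 1")
        for s in self.setting_mix:
            if self.setting_mix[s] > 0 and s not in self.note_type_mix:
                raise ValueError(f"note_type_mix missing setting {s.value!r}")
        for pos in Position:
            if pos not in self.p_note_annotated:
                raise ValueError(f"p_note_annotated missing position {pos.value!r}")
        for p in (self.note_dropout, self.annotator_flip_rate, self.p_historic_attribute,
                  self.p_second_class):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for m in self.sentences_per_note.values():
            if m < 1.0:
                raise ValueError("sentences_per_note means must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def to_yaml(self, path: str | Path) -> None:
        raw = yaml.safe_load(self.model_dump_json())
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


def study_calibrated_config(**overrides) -> SimConfig:
    """The default configuration, calibrated to the development study.

    Expected marginals under these defaults match the study design: 20
    patients per group, annotatable fractions of 0.80/0.90/0.95/1.00/0.45
    (expected annotated total 82/100), and per-note-type sentence means
    matching the observed note-yield table.
    """
    return SimConfig(**overrides)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _truncated_poisson(rng: np.random.Generator, lam: float, low: int, high: int) -> int:
    """Poisson(lam) conditioned on low <= k <= high, by rejection."""
    if lam <= 0:
        return low
    for _ in range(10_000):
        k = int(rng.poisson(lam))
        if low <= k <= high:
            return k
    raise RuntimeError("truncated Poisson rejection failed")  # pragma: no cover


def _shifted_negbin(rng: np.random.Generator, mean: float, size: float) -> int:
    """1 + NB with overall mean ``mean`` (support >= 1)."""
    m = mean - 1.0
    if m <= 0:
        return 1
    p = size / (size + m)
    return 1 + int(rng.negative_binomial(size, p))


def _choice(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs.keys())
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _covering_classes(
    rng: np.random.Generator, criteria: frozenset[int], crosswalk: Crosswalk
) -> list[str]:
    """One scoring class per drawn criterion, never endorsing outside the set."""
    chosen: list[str] = []
    covered: set[int] = set()
    for c in sorted(criteria):
        if c in covered:
            continue
        candidates = [
            cls
            for cls in crosswalk.classes_for_criterion(c)
            if cls.criteria <= criteria and not cls.criteria_require
        ]
        if not candidates:
            raise SimConfigError(
                f"criterion {c} not coverable within drawn set {sorted(criteria)} "
                "by any unrestricted scoring class of the crosswalk"
            )
        pick = candidates[rng.integers(len(candidates))]
        chosen.append(pick.name)
        covered |= pick.criteria
    return chosen


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def simulate(
    config: SimConfig,
    crosswalk: Optional[Crosswalk] = None,
    seed: Optional[int] = None,
) -> tuple[Corpus, pd.DataFrame]:
    """Generate an annotated corpus and its per-patient ground truth.

    Returns ``(corpus, truth)`` where ``truth`` has one row per patient:
    ``patient_id, group, index_reason, annotatable, true_criteria`` (";"
    joined), ``true_score, true_category, forced``.  Determinism: identical
    ``(config, seed)`` produce byte-identical corpora.
    """
    crosswalk = crosswalk or default_crosswalk()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # fail fast if the crosswalk cannot cover criteria the config may draw
    covered = crosswalk.covered_criteria()
    drawable = {
        c
        for g, mix in config.criterion_count.items()
        if g in config.group_sizes and mix.p_zero < 1.0
        for c in range(1, 12)
    }
    if drawable and not drawable <= covered:
        raise SimConfigError(
            f"crosswalk covers criteria {sorted(covered)} but the config can draw "
            f"{sorted(drawable - covered)}"
        )

    force_names = [
        c.name for c in crosswalk.classes if c.force_category is SeverityCategory.severe
    ]
    treatment_class = force_names[0] if force_names else None
    noise_names = [n for n in config.noise_class_rates if n in crosswalk]
    if set(config.noise_class_rates) - set(noise_names):
        raise SimConfigError(
            f"noise classes not in crosswalk: {sorted(set(config.noise_class_rates) - set(noise_names))}"
        )

    corpus = Corpus(provenance={"source": "synthetic", "seed": int(seed)})
    truth_rows = []
    dropped: list[str] = []

    for group in config.group_sizes:
        for i in range(config.group_sizes[group]):
            pid = f"{group.value}-{i:04d}"
            reason = (
                IndexReason.oud_diagnosis
                if rng.random() < config.p_index_oud_diagnosis[group]
                else IndexReason.opioid_order
            )
            patient = Patient(patient_id=pid, group=group, index_reason=reason)
            corpus.patients[pid] = patient

            annotatable = rng.random() < config.p_annotatable[group]

            # --- latent severity -----------------------------------------
            classes: list[str] = []
            criteria: frozenset[int] = frozenset()
            forced = False
            if annotatable:
                mix = config.criterion_count[group]
                if rng.random() >= mix.p_zero:
                    k = _truncated_poisson(rng, mix.lam, 1, 11)
                    criteria = frozenset(
                        int(c) for c in rng.choice(np.arange(1, 12), size=k, replace=False)
                    )
                    classes.extend(_covering_classes(rng, criteria, crosswalk))
                if treatment_class is not None and rng.random() < config.p_treatment[group]:
                    classes.append(treatment_class)
                    forced = True
                for name in noise_names:
                    if rng.random() < config.noise_class_rates[name]:
                        classes.append(name)
                if not classes:  # annotatable patients carry >= 1 class
                    classes.append(noise_names[0] if noise_names else crosswalk.class_names[0])

            true_score = len(criteria)
            truth_rows.append(
                (
                    pid,
                    group.value,
                    reason.value,
                    annotatable,
                    ";".join(str(c) for c in sorted(criteria)),
                    true_score,
                    categorize(true_score, forced=forced, severe_min=SEVERE_MIN_SCORE).value
                    if annotatable
                    else SeverityCategory.none.value,
                    forced,
                )
            )

            # --- chart structure ------------------------------------------
            if annotatable:
                positions = [Position.historic, Position.index, Position.new]
            else:
                n_enc = int(rng.choice([1, 2, 3], p=[0.45, 0.35, 0.2]))
                positions = [Position.index, Position.new, Position.historic][:n_enc]
            notes: list[tuple[Note, Position]] = []
            for j, pos in enumerate(positions):
                setting = _choice(rng, config.setting_mix)
                eid = f"{pid}-e{j}"
                corpus.encounters[eid] = Encounter(
                    encounter_id=eid, patient_id=pid, position=pos, setting=setting
                )
                n_notes = 1 + int(rng.poisson(config.extra_notes_rate))
                for m in range(n_notes):
                    ntype = _choice(rng, config.note_type_mix[setting])
                    note = Note(
                        note_id=f"{eid}-n{m}", encounter_id=eid, note_type=ntype, sentences=()
                    )
                    notes.append((note, pos))

            # --- place annotations ----------------------------------------
            if annotatable:
                flags = [rng.random() < config.p_note_annotated[pos] for _, pos in notes]
                if not any(flags):
                    idx = next(
                        k for k, (_, pos) in enumerate(notes) if pos is Position.index
                    )
                    flags[idx] = True
                slots: list[tuple[int, int]] = []  # (note index, sentence index)
                n_sent: dict[int, int] = {}
                for k, (note, _) in enumerate(notes):
                    if not flags[k]:
                        continue
                    n_sent[k] = _shifted_negbin(
                        rng,
                        config.sentences_per_note[note.note_type],
                        config.sentence_dispersion,
                    )
                for k, cnt in n_sent.items():
                    slots.extend((k, s) for s in range(cnt))
                order = rng.permutation(len(slots))
                sentence_classes: dict[tuple[int, int], list[str]] = {
                    slots[o]: [] for o in range(len(slots))
                }
                # every chosen class appears at least once; when classes
                # outnumber sentences they stack as multi-label sentences,
                # keeping the sentence-count distribution untouched
                for ci, cls_name in enumerate(classes):
                    sentence_classes[slots[order[ci % len(slots)]]].append(cls_name)
                pool = classes
                for o in order[len(classes):]:
                    slot = slots[o]
                    picked = pool[rng.integers(len(pool))]
                    sentence_classes[slot].append(picked)
                    if len(pool) > 1 and rng.random() < config.p_second_class:
                        other = pool[rng.integers(len(pool))]
                        if other not in sentence_classes[slot]:
                            sentence_classes[slot].append(other)

                new_notes: list[Note] = []
                for k, (note, _) in enumerate(notes):
                    if not flags[k]:
                        new_notes.append(
                            note.model_copy(
                                update={
                                    "sentences": tuple(
                                        Sentence(
                                            sentence_id=f"{note.note_id}-s{s}", text="[sent]"
                                        )
                                        for s in range(1 + int(rng.poisson(1.0)))
                                    )
                                }
                            )
                        )
                        continue
                    sentences = []
                    for s in range(n_sent[k]):
                        anns = []
                        for cls_name in sentence_classes[(k, s)]:
                            attrs = {}
                            cls = crosswalk[cls_name]
                            if "temporality" in cls.attributes:
                                attrs["temporality"] = (
                                    "historic"
                                    if rng.random() < config.p_historic_attribute
                                    else "current"
                                )
                            anns.append(
                                Annotation(
                                    annotator_id=GOLD_ANNOTATOR,
                                    class_name=cls_name,
                                    attributes=attrs,
                                )
                            )
                        sentences.append(
                            Sentence(
                                sentence_id=f"{note.note_id}-s{s}",
                                text="[sent]",
                                annotations=tuple(anns),
                            )
                        )
                    new_notes.append(note.model_copy(update={"sentences": tuple(sentences)}))
                notes = [(n, p) for n, (_, p) in zip(new_notes, notes)]
            else:
                notes = [
                    (
                        note.model_copy(
                            update={
                                "sentences": tuple(
                                    Sentence(sentence_id=f"{note.note_id}-s{s}", text="[sent]")
                                    for s in range(1 + int(rng.poisson(1.0)))
                                )
                            }
                        ),
                        pos,
                    )
                    for note, pos in notes
                ]

            for note, _ in notes:
                if config.note_dropout > 0 and rng.random() < config.note_dropout:
                    dropped.append(note.note_id)
                    continue
                corpus.notes.append(note)

    if config.annotator_flip_rate > 0:
        _add_annotator_layers(rng, corpus, crosswalk, config.annotator_flip_rate)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "group",
            "index_reason",
            "annotatable",
            "true_criteria",
            "true_score",
            "true_category",
            "forced",
        ],
    )
    corpus.provenance["n_dropped_notes"] = len(dropped)
    return corpus.validate(), truth


def _add_annotator_layers(
    rng: np.random.Generator, corpus: Corpus, crosswalk: Crosswalk, flip: float
) -> None:
    """Derive imperfect annotator layers A1/A2 from the gold layer.

    Each annotator independently misses a gold unit with probability
    ``flip`` and, with probability ``flip / 2``, adds a spurious class to an
    annotated sentence — a symmetric perturbation used only to exercise the
    agreement module.
    """
    names = list(crosswalk.class_names)
    for note in corpus.notes:
        new_sentences = []
        for s in note.sentences:
            gold = [a for a in s.annotations if a.annotator_id == GOLD_ANNOTATOR]
            extra: list[Annotation] = []
            for annotator in ("A1", "A2"):
                for a in gold:
                    if rng.random() >= flip:
                        extra.append(
                            Annotation(
                                annotator_id=annotator,
                                class_name=a.class_name,
                                attributes=dict(a.attributes),
                            )
                        )
                if gold and rng.random() < flip / 2:
                    extra.append(
                        Annotation(
                            annotator_id=annotator,
                            class_name=names[rng.integers(len(names))],
                        )
                    )
            new_sentences.append(
                s.model_copy(update={"annotations": tuple(gold) + tuple(extra)})
            )
        note.sentences = tuple(new_sentences)


def drop_notes(corpus: Corpus, rate: float, seed: int) -> Corpus:
    """Return a copy of the corpus with each note kept with prob 1 - rate.

    Patients and encounters are preserved, so scores computed on the
    sub-corpus can only fall (never rise) relative to the full corpus.
    """
    rng = np.random.default_rng(seed)
    kept = [n for n in corpus.notes if rng.random() >= rate]
    return Corpus(
        patients=dict(corpus.patients),
        encounters=dict(corpus.encounters),
        notes=kept,
        provenance={**corpus.provenance, "note_dropout": rate},
    ).validate()
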