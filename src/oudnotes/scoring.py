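"""DSM-5 criterion-count severity scoring of annotated patient charts.

A patient's severity score is the number of distinct DSM-5 criteria endorsed
by the union of their annotated classes, pooled over all notes and
encounters (criterion endorsement is binary per patient).  Scores run 0-11
and map onto severity categories:

=========  ============
score      category
=========  ============
0-1        none
2-3        mild
4-5        moderate
>= 6       severe
=========  ============

A documented force-severe class (``OUD treatment`` in the default crosswalk)
overrides the category to *severe* regardless of the criterion count; the
numeric score is left untouched so it stays interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .corpus import GOLD_ANNOTATOR, Corpus, annotation_table
from .schema import Crosswalk, SeverityCategory, criteria_for, force_severe_classes

__all__ = [
    "SEVERE_MIN_SCORE",
    "SeverityResult",
    "CorpusScores",
    "categorize",
    "score_patient",
    "score_corpus",
    "scores_to_frame",
]

#: Lowest score classified as severe.  The DSM-5 convention (>= 6) is used;
#: override per call for sensitivity analyses.
SEVERE_MIN_SCORE = 6


def categorize(
    score: int, forced: bool = False, severe_min: int = SEVERE_MIN_SCORE
) -> SeverityCategory:
    """Map a criterion count to a severity category.

    ``forced=True`` returns *severe* regardless of the score (category
    override by a force-severe class such as documented OUD treatment).
    """
    if not 0 <= score <= 11:
        raise ValueError(f"score {score} outside 0..11")
    if forced or score >= severe_min:
        return SeverityCategory.severe
    if score >= 4:
        return SeverityCategory.moderate
    if score >= 2:
        return SeverityCategory.mild
    return SeverityCategory.none


@dataclass(frozen=True)
class SeverityResult:
    """Per-patient scoring outcome."""

    patient_id: str
    endorsed_criteria: frozenset[int]
    score: int
    category: SeverityCategory
    forced: bool
    n_notes_annotated: int = 0
    n_sentences_annotated: int = 0

    def __post_init__(self) -> None:
        if self.score != len(self.endorsed_criteria):
            raise ValueError("score must equal |endorsed_criteria|")


ClassesArg = Iterable[Union[str, tuple[str, Mapping[str, str]]]]


def score_patient(
    classes: ClassesArg,
    crosswalk: Crosswalk,
    patient_id: str = "",
    n_notes_annotated: int = 0,
    n_sentences_annotated: int = 0,
    severe_min: int = SEVERE_MIN_SCORE,
) -> SeverityResult:
    """Score one patient from the multiset of their annotated classes.

    ``classes`` is an iterable of class names, or of ``(name, attributes)``
    pairs when attribute-restricted crosswalk mappings should apply.
    Duplicates are irrelevant (set semantics).  Unknown classes raise
    ``KeyError`` listing every offender.
    """
    names: list[str] = []
    attr_pairs: list[tuple[str, Mapping[str, str]]] = []
    for item in classes:
        if isinstance(item, str):
            names.append(item)
            attr_pairs.append((item, {}))
        else:
            name, attrs = item
            names.append(name)
            attr_pairs.append((name, attrs or {}))
    unknown = sorted({n for n in names if n not in crosswalk})
    if unknown:
        raise KeyError(f"unknown annotation class(es): {unknown}")

    # endorsement is per-annotation so that attribute restrictions apply to
    # the annotation that carries the attribute, then unioned per patient
    endorsed: set[int] = set()
    for name, attrs in attr_pairs:
        endorsed |= crosswalk[name].endorsed_criteria(attrs)

    forced = bool(set(names) & force_severe_classes(crosswalk))
    score = len(endorsed)
    return SeverityResult(
        patient_id=patient_id,
        endorsed_criteria=frozenset(endorsed),
        score=score,
        category=categorize(score, forced=forced, severe_min=severe_min),
        forced=forced,
        n_notes_annotated=n_notes_annotated,
        n_sentences_annotated=n_sentences_annotated,
    )


SCORE_COLUMNS = [
    "patient_id",
    "group",
    "index_reason",
    "score",
    "category",
    "forced",
    "endorsed_criteria",
    "n_notes_annotated",
    "n_sentences_annotated",
]


@dataclass
class CorpusScores:
    """Output of :func:`score_corpus`.

    ``scores`` has one row per patient *with* annotations; ``unscored``
    lists sampled patients whose notes yielded no annotations (they receive
    no score rather than an implicit zero).
    """

    scores: pd.DataFrame
    unscored: pd.DataFrame


def score_corpus(
    corpus: Corpus,
    crosswalk: Crosswalk,
    annotator_id: str | Sequence[str] = GOLD_ANNOTATOR,
    severe_min: int = SEVERE_MIN_SCORE,
) -> CorpusScores:
    """Score every annotated patient in a corpus from one annotator layer."""
    table = annotation_table(corpus, annotator_id)
    rows = []
    annotated_ids: set[str] = set()
    if not table.empty:
        for pid, sub in table.groupby("patient_id", sort=True):
            annotated_ids.add(str(pid))
            pairs = [
                (r.class_name, _parse_attrs(r.attributes))
                for r in sub.itertuples(index=False)
            ]
            res = score_patient(
                pairs,
                crosswalk,
                patient_id=str(pid),
                n_notes_annotated=int(sub["note_id"].nunique()),
                n_sentences_annotated=int(
                    sub[["note_id", "sentence_id"]].drop_duplicates().shape[0]
                ),
                severe_min=severe_min,
            )
            pat = corpus.patients[str(pid)]
            rows.append(
                (
                    res.patient_id,
                    pat.group.value,
                    pat.index_reason.value,
                    res.score,
                    res.category.value,
                    res.forced,
                    ";".join(str(c) for c in sorted(res.endorsed_criteria)),
                    res.n_notes_annotated,
                    res.n_sentences_annotated,
                )
            )
    scores = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    unscored_rows = [
        (p.patient_id, p.group.value, p.index_reason.value)
        for p in corpus.patients.values()
        if p.patient_id not in annotated_ids
    ]
    unscored = pd.DataFrame(
        sorted(unscored_rows), columns=["patient_id", "group", "index_reason"]
    )
    return CorpusScores(scores=scores, unscored=unscored)


def _parse_attrs(serialized: str) -> dict[str, str]:
    if not serialized:
        return {}
    out = {}
    for part in serialized.split(";"):
        k, _, v = part.partition("=")
        out[k] = v
    return out


def scores_to_frame(results: Iterable[SeverityResult]) -> pd.DataFrame:
    """Tabulate :class:`SeverityResult` objects (no group metadata)."""
    return pd.DataFrame(
        [
            (
                r.patient_id,
                r.score,
                r.category.value,
                r.forced,
                ";".join(str(c) for c in sorted(r.endorsed_criteria)),
            )
            for r in results
        ],
        columns=["patient_id", "score", "category", "forced", "endorsed_criteria"],
    )
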