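"""Interannotator agreement at sentence-class granularity.

Two annotators independently assign classes to sentences; the agreement
unit is the ``(note_id, sentence_id, class)`` triple (optionally including
the attribute assignment in *strict* mode).  Chance-corrected coefficients
are ill-defined for open multi-label sentence annotation, so agreement is
reported as positive percent agreement over units:

* ``positive_agreement`` (Jaccard): ``100 * |A ∩ B| / |A ∪ B|``
* ``f1`` (Dice):                    ``100 * 2|A ∩ B| / (|A| + |B|)``

Both are defined as 100 when both annotators found nothing.  Batches follow
the review workflow: notes were reviewed in batches grouped by note type,
with discordant units adjudicated into the consensus ("gold") layer after
each batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .corpus import Corpus, annotation_table

__all__ = [
    "AgreementError",
    "BatchAgreement",
    "set_agreement",
    "batch_agreement",
    "agreement_by_batch",
    "discordance_report",
]

METRICS = ("positive_agreement", "f1")

Unit = tuple  # (note_id, sentence_id, class[, attributes])


class AgreementError(ValueError):
    """Annotation sets cannot be compared (e.g. units outside the batch)."""


@dataclass(frozen=True)
class BatchAgreement:
    """Agreement summary for one batch of notes."""

    batch_id: str
    note_type: Optional[str]
    n_notes: int
    n_units_a1: int
    n_units_a2: int
    n_agree: int
    agreement_pct: float
    metric: str


def _pct(n_inter: int, n_a: int, n_b: int, metric: str) -> float:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if n_a == 0 and n_b == 0:
        return 100.0
    if metric == "positive_agreement":
        union = n_a + n_b - n_inter
        return 100.0 * n_inter / union
    return 100.0 * 2 * n_inter / (n_a + n_b)


def set_agreement(units_a: set, units_b: set, metric: str = "positive_agreement") -> float:
    """Percent agreement between two raw unit sets."""
    return _pct(len(units_a & units_b), len(units_a), len(units_b), metric)


def annotation_units(table: pd.DataFrame, include_attributes: bool = False) -> set[Unit]:
    """Distinct agreement units in an annotation table."""
    if table.empty:
        return set()
    cols = ["note_id", "sentence_id", "class_name"]
    if include_attributes:
        cols.append("attributes")
    return set(map(tuple, table[cols].itertuples(index=False, name=None)))


def batch_agreement(
    table_a1: pd.DataFrame,
    table_a2: pd.DataFrame,
    metric: str = "positive_agreement",
    include_attributes: bool = False,
    batch_id: str = "batch",
    note_type: Optional[str] = None,
    note_ids: Optional[Iterable[str]] = None,
) -> BatchAgreement:
    """Agreement between two annotators' tables over one batch of notes.

    When ``note_ids`` is given it declares the batch membership: any
    annotated unit outside it raises :class:`AgreementError` (guards against
    accidentally comparing different batches).  An annotator legitimately
    finding nothing in a batch note is not an error.
    """
    units_a = annotation_units(table_a1, include_attributes)
    units_b = annotation_units(table_a2, include_attributes)
    if note_ids is not None:
        allowed = set(note_ids)
        stray = {u[0] for u in units_a | units_b} - allowed
        if stray:
            raise AgreementError(
                f"annotations on notes outside the declared batch: {sorted(stray)}"
            )
        n_notes = len(allowed)
    else:
        n_notes = len({u[0] for u in units_a | units_b})
    n_inter = len(units_a & units_b)
    return BatchAgreement(
        batch_id=batch_id,
        note_type=note_type,
        n_notes=n_notes,
        n_units_a1=len(units_a),
        n_units_a2=len(units_b),
        n_agree=n_inter,
        agreement_pct=_pct(n_inter, len(units_a), len(units_b), metric),
        metric=metric,
    )


def agreement_by_batch(
    corpus: Corpus,
    annotator_1: str,
    annotator_2: str,
    batch_key: str = "note_type",
    metric: str = "positive_agreement",
    include_attributes: bool = False,
) -> pd.DataFrame:
    """Per-batch agreement across a corpus, batched by ``batch_key``.

    The default batching groups notes by note type, mirroring a review
    workflow in which consecutive batches alternate note types.  Returns one
    row per batch with unit counts and the agreement percentage.
    """
    t1 = annotation_table(corpus, annotator_1)
    t2 = annotation_table(corpus, annotator_2)
    if batch_key == "note_type":
        batches: dict[str, list[str]] = {}
        for n in corpus.notes:
            batches.setdefault(n.note_type.value, []).append(n.note_id)
    else:
        raise ValueError(f"unsupported batch_key {batch_key!r}")

    rows = []
    for batch_id in sorted(batches):
        ids = batches[batch_id]
        ba = batch_agreement(
            t1[t1["note_id"].isin(ids)],
            t2[t2["note_id"].isin(ids)],
            metric=metric,
            include_attributes=include_attributes,
            batch_id=batch_id,
            note_type=batch_id,
            note_ids=ids,
        )
        rows.append(
            (
                ba.batch_id,
                ba.note_type,
                ba.n_notes,
                ba.n_units_a1,
                ba.n_units_a2,
                ba.n_agree,
                ba.agreement_pct,
                ba.metric,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "batch_id",
            "note_type",
            "n_notes",
            "n_units_a1",
            "n_units_a2",
            "n_agree",
            "agreement_pct",
            "metric",
        ],
    )


def discordance_report(
    table_a1: pd.DataFrame,
    table_a2: pd.DataFrame,
    annotator_1: str = "A1",
    annotator_2: str = "A2",
    include_attributes: bool = False,
) -> pd.DataFrame:
    """Units annotated by exactly one annotator, for adjudication.

    Returns the symmetric difference ordered by note then sentence, with an
    ``only_in`` column naming the annotator who produced the unit.
    """
    units_a = annotation_units(table_a1, include_attributes)
    units_b = annotation_units(table_a2, include_attributes)
    cols = ["note_id", "sentence_id", "class_name"] + (
        ["attributes"] if include_attributes else []
    )
    rows = [(*u, annotator_1) for u in units_a - units_b] + [
        (*u, annotator_2) for u in units_b - units_a
    ]
    report = pd.DataFrame(rows, columns=cols + ["only_in"])
    return report.sort_values(["note_id", "sentence_id", "class_name"]).reset_index(
        drop=True
    )
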