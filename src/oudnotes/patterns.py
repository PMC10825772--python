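"""Documentation-pattern analytics.

Where and how OUD-relevant information appears in charts: class frequencies
cross-tabulated against note type, encounter setting, and encounter
position; per-note-type yield (how many notes of each type contain any
relevant sentence, and how densely); and two class-pair summaries — the
correlation of class frequency profiles across note types, and patient-level
co-occurrence counts.

Counting conventions: frequency matrices count *class events* (a sentence
bearing two classes contributes two), matching "class frequency" heatmaps;
note yield counts *distinct annotated sentences*.  Undefined statistics
(zero-variance rows, empty note types) are emitted as missing values, never
as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import GOLD_ANNOTATOR, Corpus, NoteType, Position, Setting, annotation_table
from .schema import Crosswalk

__all__ = [
    "FrequencyMatrix",
    "PairMatrix",
    "frequency_matrix",
    "note_yield",
    "pair_correlation",
    "patient_cooccurrence",
    "plot_heatmap",
]

AXES = {
    "note_type": [t.value for t in NoteType],
    "setting": [s.value for s in Setting],
    "position": [p.value for p in Position],
}


@dataclass
class FrequencyMatrix:
    """Class x category count matrix with margins."""

    counts: pd.DataFrame  # rows: classes, cols: closed category set
    axis: str

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class PairMatrix:
    """Symmetric class x class matrix (correlation or co-occurrence)."""

    values: pd.DataFrame
    mode: str  # "correlation_across_note_types" | "patient_cooccurrence"


def frequency_matrix(
    table: pd.DataFrame,
    axis: str = "note_type",
    crosswalk: Optional[Crosswalk] = None,
) -> FrequencyMatrix:
    """Cross-tabulate class events against one documentation axis.

    The column set is closed (11 note types, 4 settings, 3 positions) and
    zero-filled.  Rows are the classes observed in the table, or the full
    crosswalk class list when a crosswalk is supplied.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    cols = AXES[axis]
    row_index = list(crosswalk.class_names) if crosswalk is not None else sorted(
        table["class_name"].unique()
    ) if not table.empty else []
    if table.empty:
        counts = pd.DataFrame(0, index=row_index, columns=cols, dtype=int)
    else:
        counts = (
            pd.crosstab(table["class_name"], table[axis])
            .reindex(index=row_index or None, columns=cols, fill_value=0)
            .fillna(0)
            .astype(int)
        )
    counts.index.name = "class_name"
    counts.columns.name = axis
    return FrequencyMatrix(counts=counts, axis=axis)


def note_yield(corpus: Corpus, annotator_id: str = GOLD_ANNOTATOR) -> pd.DataFrame:
    """Per-note-type yield statistics.

    One row per note type (the closed 11-type set), with total note count,
    count and percentage of notes having at least one annotated sentence,
    counts of annotated notes by setting, total annotated sentences, and the
    mean/SD of annotated sentences per annotated note (NaN when no note of
    the type is annotated).
    """
    table = annotation_table(corpus, annotator_id)
    note_rows = []
    for note in corpus.notes:
        enc = corpus.encounters[note.encounter_id]
        note_rows.append((note.note_id, note.note_type.value, enc.setting.value))
    notes = pd.DataFrame(note_rows, columns=["note_id", "note_type", "setting"])

    if table.empty:
        sent_per_note = pd.Series(dtype=int)
    else:
        sent_per_note = (
            table[["note_id", "sentence_id"]]
            .drop_duplicates()
            .groupby("note_id")
            .size()
        )

    rows = []
    for nt in AXES["note_type"]:
        sub = notes[notes["note_type"] == nt]
        annotated = sub[sub["note_id"].isin(sent_per_note.index)]
        counts = sent_per_note.reindex(annotated["note_id"])
        n_notes = int(len(sub))
        n_annot = int(len(annotated))
        row = {
            "note_type": nt,
            "n_notes": n_notes,
            "n_annotated_notes": n_annot,
            "pct_annotated": 100.0 * n_annot / n_notes if n_notes else float("nan"),
            "n_sentences_annotated": int(counts.sum()) if n_annot else 0,
            "mean_sentences": float(counts.mean()) if n_annot else float("nan"),
            "sd_sentences": float(counts.std(ddof=1)) if n_annot > 1 else float("nan"),
        }
        for setting in AXES["setting"]:
            row[f"n_annotated_{setting}"] = int((annotated["setting"] == setting).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def pair_correlation(
    freq: FrequencyMatrix | pd.DataFrame, method: str = "pearson"
) -> PairMatrix:
    """Correlation of class frequency profiles across note types.

    Each class is a vector of counts over the note-type columns; cell (i, j)
    is the Pearson or Spearman correlation of the two vectors.  High values
    mean two classes are documented with similar frequency profiles across
    note types.  Zero-variance classes yield NaN rows/columns (flagged, not
    zeroed); the diagonal is 1 where defined.
    """
    counts = freq.counts if isinstance(freq, FrequencyMatrix) else freq
    if counts.shape[1] < 2:
        raise ValueError("pair correlation needs at least 2 columns")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    corr = counts.T.astype(float).corr(method=method)
    variances = counts.astype(float).var(axis=1)
    defined = variances > 0
    corr.loc[~defined, :] = np.nan
    corr.loc[:, ~defined] = np.nan
    diag = np.where(defined.to_numpy(), 1.0, np.nan)
    for i in range(len(corr)):
        corr.iloc[i, i] = diag[i]
    return PairMatrix(values=corr, mode="correlation_across_note_types")


def patient_cooccurrence(table: pd.DataFrame) -> PairMatrix:
    """Patient-level class co-occurrence counts.

    Cell (i, j) is the number of patients with at least one annotation of
    class i *and* at least one of class j; the diagonal is the per-class
    patient count.
    """
    if table.empty:
        empty = pd.DataFrame(dtype=int)
        return PairMatrix(values=empty, mode="patient_cooccurrence")
    presence = (
        table[["patient_id", "class_name"]]
        .drop_duplicates()
        .assign(present=1)
        .pivot(index="patient_id", columns="class_name", values="present")
        .fillna(0)
        .astype(int)
    )
    co = presence.T @ presence
    co.index.name = co.columns.name = "class_name"
    return PairMatrix(values=co, mode="patient_cooccurrence")


def plot_heatmap(matrix: FrequencyMatrix | PairMatrix, path: str) -> None:
    """Convenience heatmap PNG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.counts if isinstance(matrix, FrequencyMatrix) else matrix.values
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * values.shape[1] + 2), max(3, 0.3 * values.shape[0] + 1))
    )
    im = ax.imshow(values.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(values.shape[1]), labels=[str(c) for c in values.columns], rotation=90)
    ax.set_yticks(range(values.shape[0]), labels=[str(r) for r in values.index], fontsize=7)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
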