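"""Characterise where OUD-relevant information lives in a note corpus.

Simulates a calibrated corpus and prints: class-frequency mass by encounter
position, the note-yield table (which note types contain annotations and
how densely), the most correlated class pairs across note types, and the
most frequently co-occurring class pairs across patients.
"""

import numpy as np

from oudnotes import (
    annotation_table,
    default_crosswalk,
    frequency_matrix,
    note_yield,
    pair_correlation,
    patient_cooccurrence,
    simulate,
    study_calibrated_config,
)

crosswalk = default_crosswalk()
corpus, _ = simulate(study_calibrated_config(), crosswalk, seed=7)
table = annotation_table(corpus)

pos = frequency_matrix(table, "position")
share = (100 * pos.counts.sum(axis=0) / pos.grand_total).round(1)
print("share of class events by encounter position (index-heavy by design):")
print(share.to_string(), "\n")

ny = note_yield(corpus)
ny_view = ny[ny["n_notes"] > 0][
    ["note_type", "n_notes", "n_annotated_notes", "pct_annotated", "mean_sentences"]
]
print("note yield by type (pct of notes with any annotation; mean annotated")
print("sentences per annotated note):")
print(ny_view.round(1).to_string(index=False), "\n")

corr = pair_correlation(frequency_matrix(table, "note_type"))
vals = corr.values.where(~np.eye(len(corr.values), dtype=bool))
top = vals.stack().sort_values(ascending=False).head(5)
print("most similar documentation profiles across note types (Pearson r):")
for (a, b), r in top[::2].items():
    print(f"  {a}  ~  {b}: r={r:.2f}")

co = patient_cooccurrence(table).values
off = co.where(~np.eye(len(co), dtype=bool))
top_co = off.stack().sort_values(ascending=False).head(5)
print("\nclass pairs most often experienced by the same patient (patient counts):")
for (a, b), n in top_co[::2].items():
    print(f"  {a}  &  {b}: {int(n)} patients")
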