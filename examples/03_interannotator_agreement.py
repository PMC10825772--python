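"""Measure interannotator agreement between two imperfect annotators.

Simulates a corpus with two annotator layers (A1, A2) derived from the
consensus layer by a symmetric 15% miss/add perturbation, then prints
per-batch percent agreement (batches grouped by note type) and the head of
the discordance list an adjudication meeting would work through.
"""

from oudnotes import (
    agreement_by_batch,
    annotation_table,
    default_crosswalk,
    discordance_report,
    simulate,
)
from oudnotes.simulate import SimConfig

crosswalk = default_crosswalk()
config = SimConfig(
    group_sizes={"OUD-DX": 20, "OUD-TX": 20}, annotator_flip_rate=0.15
)
corpus, _ = simulate(config, crosswalk, seed=11)

iaa = agreement_by_batch(corpus, "A1", "A2", metric="positive_agreement")
print("per-batch positive (Jaccard) percent agreement over (sentence, class) units:")
print(iaa[["batch_id", "n_notes", "n_units_a1", "n_units_a2", "agreement_pct"]]
      .round(1).to_string(index=False))

f1 = agreement_by_batch(corpus, "A1", "A2", metric="f1")
print(f"\nmedian agreement: jaccard {iaa['agreement_pct'].median():.1f}%, "
      f"dice/F1 {f1['agreement_pct'].median():.1f}% "
      "(Dice >= Jaccard whenever overlap is partial)")

rep = discordance_report(
    annotation_table(corpus, "A1"), annotation_table(corpus, "A2")
)
print(f"\n{len(rep)} discordant units for adjudication; first five:")
print(rep.head().to_string(index=False))
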