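"""Score a single patient's chart from its sentence-level annotations.

Builds a three-note mini-chart by hand, loads the default crosswalk, and
prints the endorsed DSM-5 criteria, the severity score, and the category.
"""

from oudnotes import default_crosswalk, score_patient
from oudnotes.schema import DSM5_CRITERIA

crosswalk = default_crosswalk()

# classes annotated anywhere in the patient's notes (duplicates are fine:
# criterion endorsement is binary per patient)
annotated_classes = [
    "opioid craving",
    "opioid withdrawal",
    "opioid withdrawal",          # repeated in a second note
    "drug seeking",
    "history of substance misuse",  # non-scoring background class
]

result = score_patient(annotated_classes, crosswalk, patient_id="example-01")

print(f"patient:           {result.patient_id}")
print(f"endorsed criteria: {sorted(result.endorsed_criteria)}")
for c in sorted(result.endorsed_criteria):
    print(f"  {c:>2}  {DSM5_CRITERIA[c]}")
print(f"severity score:    {result.score}  (number of distinct criteria, 0-11)")
print(f"category:          {result.category.value}  (0-1 none, 2-3 mild, 4-5 moderate, >=6 severe)")

# a documented OUD-treatment order forces the severe classification
forced = score_patient(annotated_classes + ["OUD treatment"], crosswalk)
print(f"\nwith 'OUD treatment' documented: score {forced.score}, "
      f"category {forced.category.value} (forced={forced.forced})")
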