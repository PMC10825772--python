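# oudnotes

Infer opioid use disorder (OUD) severity from sentence-level annotations of
clinical notes.

Clinical notes often contain the evidence for problematic opioid use —
craving, withdrawal, drug seeking, treatment orders — that diagnostic codes
miss. A practical way to exploit this is to annotate full sentences with
classes from a fixed schema, map the annotated classes onto the 11 DSM-5
diagnostic criteria for OUD through a configurable *crosswalk*, and grade
severity from the criterion count. `oudnotes` implements that framework for
clinical-informatics researchers building or validating OUD phenotypes and
NLP training corpora: the crosswalk scorer itself, evaluation of the score
(interannotator agreement, positive predictive values), documentation-pattern
analytics (which note types, settings, and encounter positions carry the
information), and a calibrated synthetic corpus generator so every stage is
testable without any real clinical data.

## The model

For patient *i* with annotated class set *C_i* (pooled over all notes and
encounters), the crosswalk *w* maps each scoring class to a subset of the
DSM-5 criteria {1, …, 11}. The severity score is the criterion count

    s_i = | ⋃_{c ∈ C_i} w(c) | ∈ {0, …, 11}

categorised per DSM-5 convention: 0–1 no OUD, 2–3 mild, 4–5 moderate,
≥ 6 severe. A documented force-severe class (``OUD treatment`` in the
default crosswalk: a medication order for OUD implies an established severe
disorder) overrides the category while leaving the score untouched.
Endorsement is binary per patient — annotating a class five times counts
once.

The score is validated as a phenotype by its positive predictive value,
PPV = (# patients inferred moderate-or-severe, i.e. s ≥ 4 or forced) /
denominator, with the denominator either the patients whose notes yielded
annotations or all sampled patients. Interannotator agreement is positive
percent agreement over (sentence, class) units per batch of notes,
`100·|A∩B|/|A∪B|` (Jaccard), with Dice/F1 as an alternative —
chance-corrected kappa is ill-defined for open multi-label sentence
annotation.

The default crosswalk ships as YAML (27 classes, 18 scoring, 12 with a
temporality attribute) with a provisional one-criterion-per-class mapping;
swap in a site-specific chart-review crosswalk without touching code.

## Worked example

```python
from oudnotes import default_crosswalk, score_patient

crosswalk = default_crosswalk()
result = score_patient(
    ["opioid craving", "opioid withdrawal", "opioid withdrawal",
     "drug seeking", "history of substance misuse"],
    crosswalk, patient_id="example-01",
)
```

prints (via `python examples/01_score_a_chart.py`):

```
endorsed criteria: [3, 4, 11]
   3  great deal of time obtaining, using, or recovering
   4  craving
  11  withdrawal
severity score:    3  (number of distinct criteria, 0-11)
category:          mild  (0-1 none, 2-3 mild, 4-5 moderate, >=6 severe)

with 'OUD treatment' documented: score 3, category severe (forced=True)
```

The repeated ``opioid withdrawal`` annotation counts once; the non-scoring
background class ``history of substance misuse`` contributes no criterion;
the treatment order forces the severe classification at any score.

The other scripts in `examples/` walk through the remaining capabilities:
`02_simulate_and_evaluate.py` (calibrated simulation → scoring → per-group
PPVs and ground-truth recovery), `03_interannotator_agreement.py`
(per-batch agreement and the adjudication discordance list),
`04_documentation_patterns.py` (class frequencies by position, note yield,
class-pair correlation and patient co-occurrence).

A thin CLI mirrors the staged workflow:

```bash
oudnotes run-all --seed 42 --out-dir out/
oudnotes score --corpus corpus.jsonl --crosswalk crosswalk.yaml --out scores.csv
```

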