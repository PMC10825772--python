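# Methods

## Scope and data model

`oudnotes` operates on *annotations*, never raw text. A corpus is a
hierarchy Patient → Encounter → Note → Sentence → Annotation: patients
belong to one of five study groups (CP-RX, CP-nonRX, OUD-DX, OUD-TX,
Control) and carry an index-encounter reason (first OUD diagnosis vs most
recent opioid analgesic order); encounters sit at one of three positions
relative to the index date (historic / index / new) in one of four settings
(ED, ED-to-inpatient, outpatient, inpatient); notes are one of 11 closed
types; sentences carry zero or more class labels per annotator layer, with
the adjudicated consensus layer reserved under the id `"gold"`. Sentence
text is optional throughout so fixtures and synthetic corpora contain no
clinical language. On disk the corpus is JSONL, one self-contained note
record per line, written in canonical (patient, encounter, note) order so
identical corpora are byte-identical.

Two counting conventions coexist and are both exposed: a sentence bearing
*k* classes is **one annotated sentence** but **k class-frequency events**.
Totals and note-yield statistics use annotated sentences; frequency
matrices use class events.

## Severity scoring

The crosswalk maps annotation classes to subsets of the 11 DSM-5 OUD
criteria. A patient's endorsed criterion set is the union over all their
annotations, pooled across notes, encounters, and positions; the score is
its cardinality and the category follows the DSM-5 bands (0–1 none, 2–3
mild, 4–5 moderate, ≥ 6 severe). Design choices:

* **Severe boundary.** Published descriptions of the banding sometimes
  leave score 6 unassigned (">6"); the DSM-5 convention ≥ 6 is adopted — a
  score of 6 must belong to a band, and the observed severe counts in the
  reference tables reconcile only under ≥ 6. `SEVERE_MIN_SCORE` is an
  overridable constant.
* **Category override, not criterion grant.** A force-severe class
  (documented OUD treatment) sets the category to severe without inflating
  the numeric score, so the score remains a criterion count.
* **Binary endorsement.** Duplicate annotations are idempotent; scoring any
  sub-corpus can only lower a score (the monotonicity/dropout property the
  tests enforce).
* **Attribute restrictions.** The config can restrict a class→criterion
  mapping to particular attribute values (e.g. `temporality: current`).
  The shipped default applies no restrictions — whether historic mentions
  should endorse criteria is genuinely open, so the default is the lenient
  reading and the mechanism is configuration.
* **Unscored ≠ zero.** Patients whose notes yield no annotations are listed
  separately rather than scored 0; the all-sampled PPV denominator is where
  they re-enter.

The shipped crosswalk is explicitly **provisional** (version
`0.1-provisional`): the true chart-review mapping is site-specific, so each
scoring class maps to the single criterion it most directly evidences
(craving→4, tolerance→10, withdrawal→11, intoxication/overdose/naloxone/
polysubstance→8, drug seeking→3, vocational consequences→5, medical
issues→9, misuse classes→1, cutback→2, social consequences→6, activities
given up→7). All stratum-level quantities the package validates against
depend only on severity categories, not on which particular criterion a
class endorses.

## Evaluation

PPV numerator = patients with category ∈ {moderate, severe} (score ≥ 4 or
forced). A `strict_gt4` switch restricts the numerator to score > 4 for
fidelity experiments; the default ≥ 4 reading is the one consistent with
"moderate or severe" and with every published PPV. Denominators: annotated
patients, or all sampled patients (requires designed per-stratum sample
sizes). PPVs are rounded half-up to two decimals; a zero denominator yields
an explicit undefined result, never 0. Index-reason strata exclude the
control group (controls are order-indexed by design and would swamp that
stratum); pooled PPVs sum numerators and denominators before dividing.

## Agreement

The agreement unit is `(note_id, sentence_id, class)`; strict mode appends
the attribute assignment, which reproduces the observation that historic/
current attribute disagreement lowers agreement. Metrics: positive percent
agreement `100·|A∩B|/|A∪B|` (default) and Dice/F1 `100·2|A∩B|/(|A|+|B|)`;
both defined as 100 when neither annotator produced units. Chance-corrected
coefficients are deliberately out of scope: with an open multi-label unit
space there is no defensible chance model. Batches group notes by note
type; an annotator finding nothing in a batch note is legitimate, so batch
membership is declared by note-id list and only units *outside* the batch
are an error.

## Documentation patterns

Frequency matrices cross-tabulate class events against closed axis sets
(11 note types, 4 settings, 3 positions), zero-filled. Note yield reports,
per type, the share of notes with any annotated sentence and the mean/SD of
annotated sentences per annotated note. Class-pair correlation correlates
raw count profiles across the 11 note-type columns (Pearson default;
Spearman offered because class scales differ by orders of magnitude);
zero-variance classes produce NaN rows, flagged rather than zeroed.
Patient co-occurrence is the binary patient×class incidence product
`Bᵀ B`, so the diagonal is per-class patient counts.

## Synthetic corpus generator

The generator's defaults *are* the reference study conditions, stored in
`data/sim_default.yaml`, not in code:

* 5 × 20 patients; per-group probability of any annotatable content
  0.80 / 0.90 / 0.95 / 1.00 / 0.45 (expected 82 annotated of 100);
* per-group index-reason mixes (8/16, 14/18, 1.0, 1.0, 0.0 probability of
  diagnosis-indexing);
* latent criterion count per patient: zero-inflated truncated Poisson
  (p_zero 0.50/0.39/0.16/0.05/1.00, rates 7.5/8.0/7.5/8.5/—), tuned so
  expected category mixes roughly match the observed bimodal none/severe
  distributions — these are approximations, not fits;
* OUD-treatment documentation probability 0.85 in OUD-TX only;
* background non-scoring class rates (substance-history 0.60, psychiatric
  0.45, tobacco 0.35, other illicit 0.25, alcohol 0.20) shared across
  groups, which is what induces broad co-occurrence of those classes;
* setting and per-setting note-type mixtures; per-note-type annotated
  sentence means matching the observed note-yield table.

Mechanism per patient: draw annotatable flag → criterion count → a uniform
criterion subset → a covering set of scoring classes whose criteria lie
*within* the drawn set (with the shipped single-criterion crosswalk the
union equals the drawn set exactly) → treatment and noise classes → three
encounters with position-weighted per-note annotation probabilities (index
0.9, new 0.6, historic 0.4; at least one annotated note is forced at the
index) → per-note sentence counts → class events scattered over sentence
slots, every chosen class emitted at least once (classes stack as
multi-label sentences if they outnumber slots, leaving the sentence-count
distribution untouched). Ground truth (criterion set, score, category,
forced flag) is recorded before any note dropout, so dropout can only lower
recovered scores. Optional annotator layers A1/A2 are derived from gold by
a symmetric miss/add perturbation and exist solely to exercise the
agreement module.

Numerical choices: sentences per annotated note are **shifted negative
binomial** (1 + NB with mean m−1, dispersion 1.2) rather than
zero-truncated NB — the shifted form has exactly the configured mean, which
the 3-standard-error parameter-recovery checks require, whereas true zero
truncation would need per-type root-finding to hit a target mean. All
randomness flows from one `numpy` `default_rng(seed)`; identical
(config, seed) pairs produce byte-identical corpora.

What the generator does **not** emulate: real clinical prose, annotator
bias structure beyond symmetric noise, correlation between criterion count
and chart length, per-encounter severity dynamics, or coded comorbidity
structure. Passing round-trip tests therefore demonstrates the pipeline's
internal consistency — scoring inverts generation — not clinical validity
on real notes.

## Reference fixtures

The study's published summary tables are encoded as data
(`oudnotes.reference`) and realised as two fixture corpora: one carrying
the group structure (patients, index reasons, severity categories, per-group
annotated note/sentence totals), one carrying the note-type × setting yield
structure (320 notes, 186 annotated, 1436 sentences). The joint
(group × index-reason × severity) distribution is not published; the
encoded joint is the feasible completion of the published margins in which
all order-indexed CP-RX patients are category-none (the alternative
completion shifts one none patient between the CP groups and changes no
published quantity). Within published score bands, fixture scores are
none→0, mild→2, moderate→4/5 alternating, severe→7 (34 patients) or 8 (14
diagnosis-indexed patients): the unique simple assignment that also
reproduces the published stratum means (5.1 noncontrol, 6.0
diagnosis-indexed, 0.6 order-indexed) and SD 3.2. Every published quantity
asserted in tests is recomputed by running the scorer/evaluator on these
fixtures, never hard-coded as an output.

## Problem sizes and limitations

Round-trip and calibration checks run at 5 × 200 patients (≈ 3,300 notes,
≈ 17,000 sentences, ≈ 2 s to generate and score), a size at which 3-SE
bands are meaningful for every group-level probability and for all but the
rarest note types. Known limitations: the provisional crosswalk's
per-criterion assignments are placeholders pending a site mapping;
agreement metrics are not chance-corrected by design; the all-sampled PPV
for index-reason strata is not computed (the sampled-but-unannotated
patients' index reasons are a property of the sampling frame, not of the
corpus); and longitudinal (per-encounter) severity trajectories and
criterion weighting are out of scope.
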