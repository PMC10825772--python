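# Default annotation schema and class -> DSM-5 criterion crosswalk.
#
# 27 classes, 18 of them scoring, 12 carrying a temporality attribute.
# The class -> criterion mapping here is PROVISIONAL (one representative
# criterion per class, chosen from the criterion each class most directly
# evidences); a site-specific chart-review crosswalk can replace this file
# without code changes.  Criterion ids: 1 larger amounts/longer than
# intended, 2 unsuccessful cutback, 3 time spent, 4 craving, 5 role
# failure, 6 social problems, 7 activities given up, 8 hazardous use,
# 9 physical/psychological problems, 10 tolerance, 11 withdrawal.
version: "0.1-provisional"
expected_counts:
  total_classes: 27
  scoring_classes: 18
  attributed_classes: 12
classes:
  # --- opioid misuse ----------------------------------------------------
  - name: OUD
    category: opioid_misuse
    scoring: true
    criteria: [1]
  - name: OUD treatment
    category: opioid_misuse
    scoring: true
    force_category: severe
  - name: opioid misuse-prescription
    category: opioid_misuse
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [1]
  - name: opioid misuse-illicit
    category: opioid_misuse
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [1]
  - name: opioid craving
    category: opioid_misuse
    scoring: true
    criteria: [4]
  - name: opioid tolerance
    category: opioid_misuse
    scoring: true
    criteria: [10]
  - name: opioid withdrawal
    category: opioid_misuse
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [11]
  - name: intoxication
    category: opioid_misuse
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [8]
  - name: naloxone
    category: opioid_misuse
    scoring: true
    criteria: [8]
  # --- lack of control --------------------------------------------------
  - name: drug seeking
    category: lack_of_control
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [3]
  - name: unsuccessful attempts to cut down
    category: lack_of_control
    scoring: true
    criteria: [2]
  - name: use more than intended
    category: lack_of_control
    scoring: true
    criteria: [1]
  # --- consequences -----------------------------------------------------
  - name: vocational consequences
    category: consequence
    scoring: true
    criteria: [5]
  - name: social consequences
    category: consequence
    scoring: true
    criteria: [6]
  - name: activities given up
    category: consequence
    scoring: true
    criteria: [7]
  - name: opioid-related medical issues
    category: consequence
    scoring: true
    criteria: [9]
  # --- substance use, non-opioid ---------------------------------------
  - name: overdose history
    category: substance_use_nonopioid
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [8]
  - name: polysubstance misuse
    category: substance_use_nonopioid
    scoring: true
    attributes: {temporality: [current, historic]}
    criteria: [8]
  - name: history of substance misuse
    category: substance_use_nonopioid
    scoring: false
    attributes: {temporality: [current, historic]}
  - name: daily tobacco use
    category: substance_use_nonopioid
    scoring: false
    attributes: {temporality: [current, historic]}
  - name: other illicit drug use
    category: substance_use_nonopioid
    scoring: false
    attributes: {temporality: [current, historic]}
  - name: alcohol misuse
    category: substance_use_nonopioid
    scoring: false
    attributes: {temporality: [current, historic]}
  - name: cannabis use
    category: substance_use_nonopioid
    scoring: false
  # --- contributing factors --------------------------------------------
  - name: psychiatric condition
    category: contributing_factor
    scoring: false
    attributes: {temporality: [current, historic]}
  - name: chronic pain condition
    category: contributing_factor
    scoring: false
  - name: family substance use
    category: contributing_factor
    scoring: false
  # --- other ------------------------------------------------------------
  - name: opioid analgesic order
    category: other
    scoring: false
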