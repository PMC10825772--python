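# Study-calibrated defaults for the synthetic annotated-corpus generator.
#
# Group-level probabilities are calibrated to the development study's
# design marginals: 5 groups of 20 patients; per-group fractions of
# patients whose notes yielded any annotation; per-group index-encounter
# reason mixes among annotated patients; sentences-per-annotated-note
# means per note type.  Criterion-count mixtures (p_zero + truncated
# Poisson rate) are tuned so expected severity-category mixes roughly
# match the observed per-group distributions; they are approximations,
# not fits.
group_sizes:
  CP-RX: 20
  CP-nonRX: 20
  OUD-DX: 20
  OUD-TX: 20
  Control: 20
p_annotatable:
  CP-RX: 0.80        # 16/20
  CP-nonRX: 0.90     # 18/20
  OUD-DX: 0.95       # 19/20
  OUD-TX: 1.00       # 20/20
  Control: 0.45      # 9/20
p_index_oud_diagnosis:
  CP-RX: 0.50        # 8/16
  CP-nonRX: 0.7778   # 14/18
  OUD-DX: 1.0
  OUD-TX: 1.0
  Control: 0.0
criterion_count:     # P(count=0) = p_zero, else 1..11 truncated Poisson(lam)
  CP-RX:    {p_zero: 0.50, lam: 7.5}
  CP-nonRX: {p_zero: 0.39, lam: 8.0}
  OUD-DX:   {p_zero: 0.16, lam: 7.5}
  OUD-TX:   {p_zero: 0.05, lam: 8.5}
  Control:  {p_zero: 1.00, lam: 0.0}
p_treatment:         # probability the OUD-treatment (force-severe) class is documented
  CP-RX: 0.0
  CP-nonRX: 0.0
  OUD-DX: 0.0
  OUD-TX: 0.85
  Control: 0.0
noise_class_rates:   # non-scoring background classes, per annotatable patient
  history of substance misuse: 0.60
  psychiatric condition: 0.45
  daily tobacco use: 0.35
  other illicit drug use: 0.25
  alcohol misuse: 0.20
setting_mix:
  ED: 0.35
  ED_to_IPT: 0.20
  OPT: 0.30
  IPT: 0.15
note_type_mix:       # per setting
  ED:        {ed: 0.35, ed_provider: 0.30, ed_triage: 0.20, ed_support_staff: 0.15}
  ED_to_IPT: {h_and_p: 0.30, discharge_summary: 0.25, ed: 0.15, ed_provider: 0.15, progress: 0.15}
  OPT:       {progress: 0.50, ancillary_progress: 0.20, outpatient_clinic: 0.10, communication: 0.10, h_and_p: 0.05, lactation: 0.05}
  IPT:       {progress: 0.70, ancillary_progress: 0.15, discharge_summary: 0.15}
sentences_per_note:  # mean annotated sentences per annotated note, by type
  progress: 9.3
  h_and_p: 7.3
  ed: 9.5
  ed_provider: 7.7
  discharge_summary: 7.5
  ed_triage: 2.4
  ancillary_progress: 2.1
  communication: 1.7
  outpatient_clinic: 13.0
  ed_support_staff: 3.5
  lactation: 1.0
sentence_dispersion: 1.2   # negative-binomial size parameter
extra_notes_rate: 0.2      # notes per encounter = 1 + Poisson(rate)
p_note_annotated:          # per note, by encounter position (index-heavy mass)
  index: 0.90
  new: 0.60
  historic: 0.40
p_historic_attribute: 0.30 # temporality=historic for attribute-bearing classes
p_second_class: 0.10       # extra class on a filler sentence (multi-label)
note_dropout: 0.0
annotator_flip_rate: 0.0
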