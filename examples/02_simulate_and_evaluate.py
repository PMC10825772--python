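"""Simulate a study-calibrated corpus, score it, and evaluate PPVs.

Generates 100 patients (5 groups of 20) with the calibrated defaults,
scores every annotated patient, and prints per-group positive predictive
values for detecting moderate-or-severe OUD under both denominators.
"""

from oudnotes import (
    default_crosswalk,
    pooled_ppv,
    ppv,
    score_corpus,
    severity_distribution,
    simulate,
    study_calibrated_config,
)

crosswalk = default_crosswalk()
config = study_calibrated_config()
corpus, truth = simulate(config, crosswalk, seed=42)
print("corpus:", corpus.counts())

scored = score_corpus(corpus, crosswalk)
print(f"{len(scored.scores)} patients scored; "
      f"{len(scored.unscored)} had no annotatable content\n")

n_sampled = {g.value: n for g, n in config.group_sizes.items()}
dists = severity_distribution(scored.scores, "group", n_sampled=n_sampled)

print(f"{'group':<10} {'none':>5} {'mild':>5} {'mod':>5} {'sev':>5} "
      f"{'PPV(annot)':>11} {'PPV(all)':>9}")
for d in dists:
    a, s = ppv(d, "annotated"), ppv(d, "all_sampled")
    print(f"{d.stratum:<10} {d.counts['none']:>5} {d.counts['mild']:>5} "
          f"{d.counts['moderate']:>5} {d.counts['severe']:>5} "
          f"{a.value if a.defined else 'N/A':>11} {s.value if s.defined else 'N/A':>9}")

noncontrol = [d for d in dists if d.stratum != "Control"]
pooled = pooled_ppv(noncontrol, "annotated")
print(f"\npooled noncontrol PPV (annotated denominator): "
      f"{pooled.value}  ({pooled.numerator}/{pooled.denominator})")
print("PPV = fraction of patients inferred moderate-or-severe among the denominator;")
print("higher values in OUD-TX/OUD-DX reflect their stronger documented evidence.")

# ground truth lets us verify the scorer recovered every simulated category
merged = scored.scores.merge(truth, on="patient_id")
acc = (merged["category"] == merged["true_category"]).mean()
print(f"ground-truth category recovery at zero note dropout: {100 * acc:.1f}%")
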