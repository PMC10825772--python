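"""Synthetic corpus generator: determinism, calibration, ground-truth recovery."""

import numpy as np
import pytest

from oudnotes import annotation_table, score_corpus, simulate, write_corpus
from oudnotes.simulate import SimConfig, SimConfigError, study_calibrated_config


class TestConfig:
    def test_defaults_validate_and_match_design(self):
        cfg = study_calibrated_config()
        assert sum(cfg.group_sizes.values()) == 100
        expected_annotated = sum(
            cfg.group_sizes[g] * cfg.p_annotatable[g] for g in cfg.group_sizes
        )
        assert expected_annotated == pytest.approx(82)
        oudtx = next(g for g in cfg.group_sizes if g.value == "OUD-TX")
        assert cfg.p_annotatable[oudtx] == 1.0

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_annotatable={g: 1.5 for g in ["CP-RX", "CP-nonRX", "OUD-DX",
                                                      "OUD-TX", "Control"]})

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="setting_mix"):
            SimConfig(setting_mix={"ED": 0.5, "ED_to_IPT": 0.2, "OPT": 0.2, "IPT": 0.2})

    def test_uncoverable_criteria_rejected(self, tmp_path):
        import yaml

        from oudnotes.schema import load_crosswalk

        p = tmp_path / "xw.yaml"
        p.write_text(
            yaml.safe_dump({"classes": [
                {"name": "only-craving", "category": "opioid_misuse",
                 "scoring": True, "criteria": [4]}]}),
            encoding="utf-8",
        )
        with pytest.raises(SimConfigError):
            simulate(SimConfig(group_sizes={"OUD-DX": 5}), load_crosswalk(p), seed=0)


class TestDeterminism:
    def test_same_seed_byte_identical(self, crosswalk, tmp_path):
        cfg = SimConfig(group_sizes={"OUD-TX": 10, "Control": 10})
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        for p in (p1, p2):
            corpus, _ = simulate(cfg, crosswalk, seed=123)
            write_corpus(corpus, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self, crosswalk, tmp_path):
        cfg = SimConfig(group_sizes={"OUD-TX": 10})
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus(simulate(cfg, crosswalk, seed=1)[0], p1)
        write_corpus(simulate(cfg, crosswalk, seed=2)[0], p2)
        assert p1.read_bytes() != p2.read_bytes()


class TestGroundTruth:
    def test_zero_dropout_recovers_every_category(self, crosswalk):
        corpus, truth = simulate(study_calibrated_config(), crosswalk, seed=42)
        scores = score_corpus(corpus, crosswalk).scores
        merged = scores.merge(truth, on="patient_id")
        assert len(merged) == int(truth["annotatable"].sum())
        assert (merged["category"] == merged["true_category"]).all()
        assert (merged["score"] == merged["true_score"]).all()

    def test_scores_never_overshoot_truth_under_dropout(self, crosswalk):
        cfg = SimConfig(group_sizes={"OUD-DX": 40}, note_dropout=0.5)
        corpus, truth = simulate(cfg, crosswalk, seed=8)
        scores = score_corpus(corpus, crosswalk).scores
        merged = scores.merge(truth, on="patient_id")
        assert (merged["score"] <= merged["true_score"]).all()

    def test_control_only_config_scores_all_zero(self, crosswalk):
        corpus, truth = simulate(SimConfig(group_sizes={"Control": 30}), crosswalk, seed=6)
        scores = score_corpus(corpus, crosswalk).scores
        assert (scores["score"] == 0).all()
        assert (truth["true_score"] == 0).all()

    def test_annotatable_flag_matches_annotation_presence(self, crosswalk):
        corpus, truth = simulate(study_calibrated_config(), crosswalk, seed=13)
        annotated = set(annotation_table(corpus)["patient_id"].unique())
        assert annotated == set(truth.loc[truth["annotatable"], "patient_id"])


@pytest.fixture(scope="module")
def big(crosswalk):
    cfg = study_calibrated_config(
        group_sizes={g: 200 for g in ["CP-RX", "CP-nonRX", "OUD-DX", "OUD-TX", "Control"]}
    )
    corpus, truth = simulate(cfg, crosswalk, seed=2024)
    return cfg, corpus, truth


class TestCalibration:
    """Empirical marginals at group size 200 stay within 3 Monte-Carlo SEs."""

    def test_annotatable_fractions(self, big):
        cfg, _, truth = big
        for group, p in cfg.p_annotatable.items():
            sub = truth[truth["group"] == group.value]
            n = len(sub)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(sub["annotatable"].mean() - p) <= max(3 * se, 1e-12), group

    def test_sentences_per_annotated_note_means(self, big, crosswalk):
        cfg, corpus, _ = big
        table = annotation_table(corpus)
        per_note = (
            table[["note_type", "note_id", "sentence_id"]]
            .drop_duplicates()
            .groupby(["note_type", "note_id"])
            .size()
            .reset_index(name="n")
        )
        for nt, target in cfg.sentences_per_note.items():
            counts = per_note.loc[per_note["note_type"] == nt.value, "n"]
            if len(counts) < 30:
                continue  # too few notes of this type for a stable mean
            se = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - target) <= 3 * se + 1e-9, nt
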