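"""Severity scoring: category thresholds, set semantics, oracle equivalence."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oudnotes import (
    SeverityCategory,
    categorize,
    criteria_for,
    score_corpus,
    score_patient,
)
from oudnotes.simulate import SimConfig, drop_notes, simulate
from .conftest import TOY_CROSSWALK as TOY
from .conftest import TOY_MAPPING


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0, "none"), (1, "none"),
            (2, "mild"), (3, "mild"),
            (4, "moderate"), (5, "moderate"),
            (6, "severe"), (11, "severe"),
        ],
    )
    def test_band_boundaries(self, score, expected):
        assert categorize(score).value == expected

    def test_forced_overrides_any_score(self):
        assert categorize(0, forced=True) is SeverityCategory.severe

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(12)
        with pytest.raises(ValueError):
            categorize(-1)


class TestScorePatient:
    def test_no_annotations(self, crosswalk):
        r = score_patient([], crosswalk)
        assert r.score == 0 and r.category is SeverityCategory.none

    def test_three_criteria_is_mild(self, crosswalk):
        r = score_patient(
            ["opioid craving", "opioid tolerance", "opioid withdrawal"], crosswalk
        )
        assert r.endorsed_criteria == frozenset({4, 10, 11})
        assert r.score == 3 and r.category is SeverityCategory.mild

    def test_treatment_forces_severe_at_any_score(self, crosswalk):
        r = score_patient(["OUD treatment"], crosswalk)
        assert r.score == 0 and r.category is SeverityCategory.severe and r.forced

    def test_duplicates_are_idempotent(self, crosswalk):
        once = score_patient(["opioid craving"], crosswalk)
        many = score_patient(["opioid craving"] * 5, crosswalk)
        assert (once.score, once.category) == (many.score, many.category)

    def test_unknown_class_lists_offenders(self, crosswalk):
        with pytest.raises(KeyError, match="bogus"):
            score_patient(["opioid craving", "bogus"], crosswalk)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(["a", "b", "c", "d", "e"])))
    def test_matches_brute_force_union_oracle(self, names):
        # oracle: enumerate criterion sets directly from the toy mapping
        mapping = TOY_MAPPING
        expected = set().union(*(mapping[n] for n in names)) if names else set()
        r = score_patient(sorted(names), TOY)
        assert r.endorsed_criteria == frozenset(expected)
        assert r.score == len(expected)
        assert r.forced == ("d" in names)

    def test_all_toy_subsets_against_oracle(self):
        mapping = TOY_MAPPING
        for k in range(6):
            for combo in itertools.combinations(mapping, k):
                expected = set().union(*(mapping[n] for n in combo)) if combo else set()
                assert score_patient(list(combo), TOY).score == len(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.sets(st.sampled_from(["a", "b", "c", "d", "e"])),
        st.sets(st.sampled_from(["a", "b", "c", "d", "e"])),
    )
    def test_monotone_under_annotation_addition(self, base, extra):
        order = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
        r1 = score_patient(sorted(base), TOY)
        r2 = score_patient(sorted(base | extra), TOY)
        assert r2.score >= r1.score
        assert order[r2.category.value] >= order[r1.category.value]

    def test_permutation_invariance(self, crosswalk):
        names = ["opioid craving", "OUD treatment", "drug seeking", "intoxication"]
        r1 = score_patient(names, crosswalk)
        r2 = score_patient(list(reversed(names)), crosswalk)
        assert r1.endorsed_criteria == r2.endorsed_criteria
        assert (r1.score, r1.category, r1.forced) == (r2.score, r2.category, r2.forced)


class TestScoreCorpus:
    def test_reference_corpus_row_counts(self, ref_scores):
        assert len(ref_scores.scores) == 82
        assert len(ref_scores.unscored) == 18
        assert (ref_scores.unscored["group"] == "Control").sum() == 11

    def test_controls_all_score_zero(self, ref_scores):
        controls = ref_scores.scores[ref_scores.scores["group"] == "Control"]
        assert (controls["score"] == 0).all()

    def test_empty_corpus(self, crosswalk):
        from oudnotes import Corpus

        res = score_corpus(Corpus(), crosswalk)
        assert res.scores.empty and res.unscored.empty

    def test_note_dropout_never_raises_scores(self, crosswalk):
        cfg = SimConfig(group_sizes={"OUD-DX": 30, "CP-RX": 30})
        corpus, _ = simulate(cfg, crosswalk, seed=5)
        full = score_corpus(corpus, crosswalk).scores.set_index("patient_id")["score"]
        for rate, sub_seed in [(0.3, 1), (0.7, 2)]:
            sub = drop_notes(corpus, rate, seed=sub_seed)
            part = score_corpus(sub, crosswalk).scores.set_index("patient_id")["score"]
            joined = part.to_frame("sub").join(full.to_frame("full"), how="left")
            assert (joined["sub"] <= joined["full"]).all()
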