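import pytest

from oudnotes import default_crosswalk, score_corpus
from oudnotes.reference import reference_corpus, reference_note_corpus
from oudnotes.schema import Crosswalk

#: 5-class toy crosswalk with overlapping criteria, a forced class, and a
#: non-scoring class — small enough for exhaustive brute-force oracles.
TOY_CROSSWALK = Crosswalk.model_validate(
    {
        "classes": [
            {"name": "a", "category": "opioid_misuse", "scoring": True, "criteria": [1, 2]},
            {"name": "b", "category": "opioid_misuse", "scoring": True, "criteria": [2, 3]},
            {"name": "c", "category": "consequence", "scoring": True, "criteria": [5]},
            {"name": "d", "category": "opioid_misuse", "scoring": True,
             "force_category": "severe"},
            {"name": "e", "category": "other", "scoring": False},
        ]
    }
)

#: the mapping above, duplicated as plain sets for independent oracles
TOY_MAPPING = {"a": {1, 2}, "b": {2, 3}, "c": {5}, "d": set(), "e": set()}


@pytest.fixture(scope="session")
def toy_crosswalk():
    return TOY_CROSSWALK


@pytest.fixture(scope="session")
def crosswalk():
    return default_crosswalk()


@pytest.fixture(scope="session")
def ref_corpus(crosswalk):
    """Fixture corpus encoding the study's group/severity summary tables."""
    return reference_corpus(crosswalk)


@pytest.fixture(scope="session")
def ref_scores(ref_corpus, crosswalk):
    return score_corpus(ref_corpus, crosswalk)


@pytest.fixture(scope="session")
def ref_note_corpus():
    """Fixture corpus encoding the per-note-type yield table."""
    return reference_note_corpus()
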