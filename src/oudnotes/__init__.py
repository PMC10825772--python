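"""oudnotes: infer opioid use disorder severity from annotated clinical notes.

The package turns sentence-level, multi-label annotations of clinical notes
into DSM-5 criterion-count severity scores via a configurable annotation
class → criterion crosswalk, evaluates the score (interannotator agreement,
positive predictive values), characterises documentation patterns (class
frequencies by note type / setting / encounter position, class-pair
correlation and patient co-occurrence), and generates synthetic annotated
corpora with known ground truth for end-to-end testing.
"""

from .agreement import (
    BatchAgreement,
    agreement_by_batch,
    batch_agreement,
    discordance_report,
    set_agreement,
)
from .corpus import (
    GOLD_ANNOTATOR,
    Annotation,
    Corpus,
    CorpusValidationError,
    Encounter,
    Group,
    IndexReason,
    Note,
    NoteType,
    Patient,
    Position,
    Sentence,
    Setting,
    annotation_table,
    read_corpus,
    write_corpus,
)
from .evaluation import (
    PPVResult,
    SeverityDistribution,
    pooled_ppv,
    ppv,
    severity_distribution,
)
from .patterns import (
    FrequencyMatrix,
    PairMatrix,
    frequency_matrix,
    note_yield,
    pair_correlation,
    patient_cooccurrence,
)
from .schema import (
    AnnotationClass,
    Crosswalk,
    SeverityCategory,
    criteria_for,
    default_crosswalk,
    force_severe_classes,
    load_crosswalk,
)
from .scoring import (
    SEVERE_MIN_SCORE,
    CorpusScores,
    SeverityResult,
    categorize,
    score_corpus,
    score_patient,
)
from .simulate import SimConfig, drop_notes, simulate, study_calibrated_config

__version__ = "0.1.0"

__all__ = [
    "__version__",
    # schema
    "AnnotationClass",
    "Crosswalk",
    "SeverityCategory",
    "criteria_for",
    "default_crosswalk",
    "force_severe_classes",
    "load_crosswalk",
    # corpus
    "GOLD_ANNOTATOR",
    "Annotation",
    "Corpus",
    "CorpusValidationError",
    "Encounter",
    "Group",
    "IndexReason",
    "Note",
    "NoteType",
    "Patient",
    "Position",
    "Sentence",
    "Setting",
    "annotation_table",
    "read_corpus",
    "write_corpus",
    # scoring
    "SEVERE_MIN_SCORE",
    "CorpusScores",
    "SeverityResult",
    "categorize",
    "score_corpus",
    "score_patient",
    # agreement
    "BatchAgreement",
    "agreement_by_batch",
    "batch_agreement",
    "discordance_report",
    "set_agreement",
    # evaluation
    "PPVResult",
    "SeverityDistribution",
    "pooled_ppv",
    "ppv",
    "severity_distribution",
    # patterns
    "FrequencyMatrix",
    "PairMatrix",
    "frequency_matrix",
    "note_yield",
    "pair_correlation",
    "patient_cooccurrence",
    # simulation
    "SimConfig",
    "drop_notes",
    "simulate",
    "study_calibrated_config",
]
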