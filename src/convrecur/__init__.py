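"""convrecur: conceptual recurrence analysis of annotated dyadic conversations.

The package quantifies *content-based conversational engagement* — the reuse
of content terms between two speakers — in coded transcripts of dyadic
conversations (a carer channel and a partner channel), and links coded carer
communication behaviours to that engagement through per-behaviour odds-ratio
and univariate logistic analyses.  A synthetic-conversation generator with
known reuse dynamics supports end-to-end testing and parameter recovery.
"""

from importlib import resources

from .transcript_io import (
    BehaviourCode,
    Conversation,
    DyadViolationError,
    EmptyTranscriptError,
    ParserConfig,
    TranscriptError,
    UnknownCodeError,
    Utterance,
    default_registry,
    extract_annotations,
    parse_transcript,
    write_conversation,
)
from .recurrence_engine import (
    METRIC_COLUMNS,
    RecurrenceMatrix,
    TermVocabulary,
    TurnVector,
    WindowSpec,
    build_vocabulary,
    default_stopwords,
    load_stopwords,
    metrics_frame,
    primitive_metrics,
    recurrence_matrix,
    render_recurrence_plot,
    similarity,
    tokenize,
    turn_vectors,
)
from .engagement_labels import (
    EngagementLabels,
    TurnRecord,
    binarize,
    build_turn_table,
    label_conversation,
    records_to_frame,
)
from .association_analysis import (
    AssociationResult,
    ContingencyTable,
    behaviour_frequencies,
    contingency,
    eligible_behaviours,
    eligibility_threshold,
    logistic_association,
    odds_ratio,
    results_table,
)
from .synthetic_data import (
    GroundTruth,
    SyntheticConfig,
    generate_conversation,
    generate_corpus,
    recovery_report,
    run_pipeline,
)

__version__ = "0.1.0"


def load_example_conversation() -> Conversation:
    """Parse the packaged 14-turn example dialogue between a care staff
    member (CS) and a person with dementia (PWD)."""
    path = resources.files("convrecur").joinpath("data/example_dialogue.csv")
    with resources.as_file(path) as p:
        return parse_transcript(p, conversation_id="example")
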