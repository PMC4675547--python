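"""Term-based conceptual recurrence: vocabulary, turn similarity, primitive metrics.

The engine quantifies how much the *content terms* of one turn recur in other
turns of the same conversation.  For each conversation a capped vocabulary of
content terms is built (stopwords excluded, most frequent terms first), every
turn becomes a binary term-presence vector, and the pairwise turn similarity
is the cosine of those binary vectors,

    sim(i, j) = shared / sqrt(m * n),

with ``shared`` the number of vocabulary terms the turns have in common and
``m``, ``n`` the turns' term counts.  From the similarity matrix, twelve
*primitive metrics* are derived per turn — every combination of

* time scale:  short (the adjacent turn), medium (a 10-turn window),
  long (all remaining turns);
* direction:   forward (later turns) or backward (earlier turns);
* type:        other (the conversation partner) or self (the same speaker).

Short metrics are the single adjacent-turn similarity (0 if the adjacent turn
is the wrong speaker type); medium and long metrics are the arithmetic mean of
the similarities to the qualifying-speaker turns actually present in the
window, and 0 when no such turn exists.  The diagonal (a turn with itself) is
never part of any window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .transcript_io import Conversation

__all__ = [
    "DEFAULT_MAX_TERMS",
    "WindowSpec",
    "TermVocabulary",
    "TurnVector",
    "RecurrenceMatrix",
    "METRIC_COLUMNS",
    "load_stopwords",
    "default_stopwords",
    "tokenize",
    "build_vocabulary",
    "turn_vectors",
    "similarity",
    "recurrence_matrix",
    "primitive_metrics",
    "metrics_frame",
    "render_recurrence_plot",
]

DEFAULT_MAX_TERMS = 200

#: Column order of the twelve primitive metrics.
METRIC_COLUMNS = [
    "other_forward_short",
    "other_forward_medium",
    "other_forward_long",
    "other_backward_short",
    "other_backward_medium",
    "other_backward_long",
    "self_forward_short",
    "self_forward_medium",
    "self_forward_long",
    "self_backward_short",
    "self_backward_medium",
    "self_backward_long",
]


@dataclass(frozen=True)
class WindowSpec:
    """Recurrence window sizes counted in raw turn distance.

    ``short`` is the adjacent-turn lag, ``medium`` the medium-range window
    width, and ``long`` is unbounded (``None`` = all remaining turns).
    """

    short: int = 1
    medium: int = 10
    long: int | None = None


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stopword list: one term per line, UTF-8, ``#`` comments."""
    words: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


_default_stopwords_cache: frozenset[str] | None = None


def default_stopwords() -> frozenset[str]:
    """The packaged default stopword list (function words, backchannels,
    common contractions and a few ambiguous conversational tokens)."""
    global _default_stopwords_cache
    if _default_stopwords_cache is None:
        text = resources.files("convrecur").joinpath("data/stopwords.txt").read_text("utf-8")
        _default_stopwords_cache = frozenset(
            line.strip().lower()
            for line in text.splitlines()
            if line.strip() and not line.strip().startswith("#")
        )
    return _default_stopwords_cache


_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "`": "'"})
_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(clean_text: str) -> list[str]:
    """Segment annotation-free text into lowercased word tokens.

    Punctuation is stripped, contractions stay single tokens (``don't``), and
    repaired false starts (``they-``) yield the bare word because the hyphen
    never joins a token.
    """
    text = clean_text.lower().translate(_APOSTROPHES)
    return [tok.strip("'") for tok in _TOKEN_RE.findall(text) if tok.strip("'")]


@dataclass(frozen=True)
class TermVocabulary:
    """Per-conversation content-term vocabulary (never pooled across conversations)."""

    terms: tuple[str, ...]
    stopwords: frozenset[str]
    max_terms: int = DEFAULT_MAX_TERMS
    source: str = ""
    index: dict[str, int] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.terms) > self.max_terms:
            raise ValueError(f"vocabulary of {len(self.terms)} exceeds cap {self.max_terms}")
        if set(self.terms) & self.stopwords:
            raise ValueError("vocabulary terms overlap the stopword set")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.terms)})

    def __len__(self) -> int:
        return len(self.terms)


def build_vocabulary(
    conv: Conversation,
    stopwords: frozenset[str] | None = None,
    max_terms: int = DEFAULT_MAX_TERMS,
) -> TermVocabulary:
    """Build the conversation's term vocabulary.

    Non-stopword tokens are ranked by descending within-conversation frequency
    (ties broken by first occurrence) and truncated to ``max_terms``.  An
    all-stopword conversation yields an empty vocabulary, under which every
    similarity is 0.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    pos = 0
    for utt in conv.utterances:
        for tok in tokenize(utt.clean_text):
            if tok in stopwords:
                pos += 1
                continue
            counts[tok] = counts.get(tok, 0) + 1
            first_seen.setdefault(tok, pos)
            pos += 1
    ranked = sorted(counts, key=lambda t: (-counts[t], first_seen[t]))
    return TermVocabulary(
        terms=tuple(ranked[:max_terms]),
        stopwords=stopwords,
        max_terms=max_terms,
        source=conv.id,
    )


@dataclass(frozen=True)
class TurnVector:
    """Binary term-presence indicator for one turn over a vocabulary."""

    utterance_index: int
    presence: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.presence, dtype=np.int64)
        if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
            raise ValueError("presence must be a 1-D binary vector")
        object.__setattr__(self, "presence", arr)


def turn_vectors(conv: Conversation, vocab: TermVocabulary) -> np.ndarray:
    """Stack the binary term-presence vectors of all turns (n_turns x |vocab|)."""
    mat = np.zeros((len(conv), len(vocab)), dtype=np.int64)
    for i, utt in enumerate(conv.utterances):
        for tok in tokenize(utt.clean_text):
            j = vocab.index.get(tok)
            if j is not None:
                mat[i, j] = 1
    return mat


def similarity(a: TurnVector | np.ndarray, b: TurnVector | np.ndarray) -> float:
    """Cosine similarity of two binary term vectors: shared / sqrt(m * n)."""
    va = a.presence if isinstance(a, TurnVector) else np.asarray(a)
    vb = b.presence if isinstance(b, TurnVector) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"vocabulary mismatch: {va.shape} vs {vb.shape}")
    m = int(va.sum())
    n = int(vb.sum())
    if m == 0 or n == 0:
        return 0.0
    shared = int((va & vb).sum())
    return float(shared / np.sqrt(m * n))


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Symmetric turn-by-turn similarity matrix with the speaker of each turn."""

    sim: np.ndarray
    speaker_of: tuple[str, ...]

    @property
    def n_turns(self) -> int:
        return len(self.speaker_of)


def recurrence_matrix(conv: Conversation, vocab: TermVocabulary) -> RecurrenceMatrix:
    """Compute all pairwise turn similarities for a conversation.

    The diagonal is 1 for turns holding at least one vocabulary term, 0 for
    contentless turns.
    """
    mat = turn_vectors(conv, vocab)
    counts = mat.sum(axis=1)
    shared = mat @ mat.T
    denom = np.sqrt(np.outer(counts, counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, shared / denom, 0.0)
    np.fill_diagonal(sim, (counts > 0).astype(float))
    return RecurrenceMatrix(sim=sim, speaker_of=tuple(u.speaker for u in conv.utterances))


def _window_mean(values: np.ndarray) -> float:
    # mean over the qualifying turns actually present; empty window -> 0
    if values.size == 0:
        return 0.0
    return float(values.sum() / values.size)


def primitive_metrics(
    m: RecurrenceMatrix, windows: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """Derive the twelve primitive recurrence metrics for every turn.

    Returns a DataFrame with one row per turn and the columns of
    :data:`METRIC_COLUMNS`.
    """
    n = m.n_turns
    sim = m.sim
    speakers = np.asarray(m.speaker_of)
    out = np.zeros((n, len(METRIC_COLUMNS)), dtype=float)

    for t in range(n):
        other = speakers != speakers[t]
        row = sim[t]

        fwd_stop = n if windows.long is None else min(n, t + windows.long + 1)
        bwd_start = 0 if windows.long is None else max(0, t - windows.long)
        fwd_med_stop = min(n, t + windows.medium + 1)
        bwd_med_start = max(0, t - windows.medium)

        for type_offset, qualify in ((0, other), (6, ~other)):
            # short: the single adjacent turn, if it is the qualifying speaker
            s_fwd = row[t + 1] if t + 1 < n and qualify[t + 1] else 0.0
            s_bwd = row[t - 1] if t - 1 >= 0 and qualify[t - 1] else 0.0

            fm_sel = row[t + 1 : fwd_med_stop][qualify[t + 1 : fwd_med_stop]]
            fl_sel = row[t + 1 : fwd_stop][qualify[t + 1 : fwd_stop]]
            bm_sel = row[bwd_med_start:t][qualify[bwd_med_start:t]]
            bl_sel = row[bwd_start:t][qualify[bwd_start:t]]

            out[t, type_offset + 0] = s_fwd
            out[t, type_offset + 1] = _window_mean(fm_sel)
            out[t, type_offset + 2] = _window_mean(fl_sel)
            out[t, type_offset + 3] = s_bwd
            out[t, type_offset + 4] = _window_mean(bm_sel)
            out[t, type_offset + 5] = _window_mean(bl_sel)

    return pd.DataFrame(out, columns=METRIC_COLUMNS)


def metrics_frame(
    conv: Conversation,
    stopwords: frozenset[str] | None = None,
    max_terms: int = DEFAULT_MAX_TERMS,
    windows: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Run the full per-conversation engine and attach turn metadata.

    Mirrors the flat per-utterance export consumed by the labelling stage:
    ``conversation_id, index, speaker, text``, the twelve metric columns and
    the semicolon-joined behaviour codes.
    """
    vocab = build_vocabulary(conv, stopwords=stopwords, max_terms=max_terms)
    metrics = primitive_metrics(recurrence_matrix(conv, vocab), windows=windows)
    meta = pd.DataFrame(
        {
            "conversation_id": conv.id,
            "index": [u.index for u in conv.utterances],
            "speaker": [u.speaker for u in conv.utterances],
            "text": [u.clean_text for u in conv.utterances],
        }
    )
    codes = pd.Series(
        [";".join(sorted(u.behaviour_codes)) for u in conv.utterances], name="behaviour_codes"
    )
    return pd.concat([meta, metrics, codes], axis=1)


def render_recurrence_plot(
    m: RecurrenceMatrix,
    conv: Conversation,
    out: str | Path,
    channel_colors: dict[str, str] | None = None,
    annotate_codes: bool = True,
    figsize_per_turn: float = 0.28,
):
    """Render the lower-triangular recurrence plot.

    Diagonal cells are coloured by speaker; a cell below the diagonal at
    (row i, column j) is shaded by sim(i, j), split into the two turns'
    speaker colours for cross-speaker recurrence.  Behaviour codes are
    written alongside their turns.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon, Rectangle

    if channel_colors is None:
        palette = ("#3b6fb6", "#c23b3b")
        channel_colors = {ch: palette[k % 2] for k, ch in enumerate(conv.channels)}

    n = m.n_turns
    size = max(2.0, n * figsize_per_turn)
    fig, ax = plt.subplots(figsize=(size, size))
    ax.set_aspect("equal")
    ax.axis("off")

    for i in range(n):
        ci = channel_colors[m.speaker_of[i]]
        ax.add_patch(Rectangle((i, -i - 1), 1, 1, facecolor=ci, edgecolor="white", lw=0.4))
        for j in range(i):
            s = float(m.sim[i, j])
            if s <= 0:
                continue
            cj = channel_colors[m.speaker_of[j]]
            # column j, row i; split the cell along its diagonal into the
            # source and target speaker colours
            x, y = j, -i - 1
            lower = Polygon([(x, y), (x + 1, y), (x + 1, y + 1)], facecolor=ci, alpha=s)
            upper = Polygon([(x, y), (x, y + 1), (x + 1, y + 1)], facecolor=cj, alpha=s)
            ax.add_patch(lower)
            ax.add_patch(upper)
    if annotate_codes:
        for i, utt in enumerate(conv.utterances):
            if utt.behaviour_codes:
                ax.annotate(
                    ";".join(sorted(utt.behaviour_codes)),
                    (i + 1.1, -i - 0.8),
                    fontsize=6,
                    va="top",
                )
    if n:
        ax.set_xlim(-0.5, n + 3)
        ax.set_ylim(-n - 0.5, 0.5)
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return out
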