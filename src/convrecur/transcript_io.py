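"""Reading, validating and writing annotated dyadic conversation transcripts.

Transcripts are two-column delimited text files (``speaker,text``) in which
each row is one speaker turn.  The text column may carry two kinds of inline
annotation:

* bracketed communication-behaviour codes, e.g. ``[ActListen]``, attached by
  human coders to the turn in which the behaviour occurred;
* parenthetical prosodic / non-verbal notations, e.g. ``(SPause)``,
  ``(laugh)``, ``(interruption)``.

Parsing separates the spoken content from both kinds of annotation, so that
downstream term-recurrence analysis sees only the words actually said, while
the behaviour codes remain available per turn for the association analyses.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviourCode",
    "Utterance",
    "Conversation",
    "ParserConfig",
    "TranscriptError",
    "DyadViolationError",
    "EmptyTranscriptError",
    "UnknownCodeError",
    "default_registry",
    "extract_annotations",
    "parse_transcript",
    "write_conversation",
    "DEFAULT_NOTATIONS",
]


class TranscriptError(ValueError):
    """Base class for transcript parsing problems."""


class DyadViolationError(TranscriptError):
    """Raised when a transcript does not resolve to exactly two speakers."""


class EmptyTranscriptError(TranscriptError):
    """Raised when a transcript contains no utterance rows."""


class UnknownCodeError(TranscriptError):
    """Raised in strict mode for a bracketed code absent from the registry."""


@dataclass(frozen=True)
class BehaviourCode:
    """A registered communication-behaviour code.

    ``category`` is ``"facilitative"`` for behaviours expected to support the
    conversation partner and ``"non-facilitative"`` for behaviours that
    represent missing or counterproductive support.
    """

    label: str
    category: str
    description: str = ""


# The default coding scheme: 22 facilitative and 13 non-facilitative
# communication behaviours used when carers talk with people with dementia.
_FACILITATIVE: dict[str, str] = {
    "VblAck": "Verbal acknowledgment: verbally acknowledge/affirm the partner's utterance",
    "ActListen": "Active listening: restate, paraphrase or build on partner content",
    "GiveTime": "Give time: leave a pause for the partner to respond or continue",
    "PWDKnowl": "Use prior knowledge of the partner's life and interests",
    "VblEncCont": "Verbal encouragement to continue (minimal continuers)",
    "Expand": "Give additional explanation, clues or clarification",
    "AnsCont": "Provide answer content, choices or examples within a question",
    "UseName": "Address the partner by name",
    "SelfDisc": "Self disclosure: share own circumstances and experiences",
    "Rephrase": "Rephrase own utterance after trouble, with different wording",
    "WorkOut": "Try to work out the partner's intended message",
    "Humour": "Utterance contains humorous content",
    "PWDTopic": "Take up a partner-initiated topic",
    "ReduceQ": "Reduce a failed open question to a yes/no or alternative question",
    "VisTopic": "Topic supported by a visual cue in the setting",
    "RephQ": "Immediately rephrase a question without changing its target",
    "SugCont": "Suggest content to help word finding or complete an utterance",
    "MixedQ": "Yes/no or alternatives question appended directly to an open question",
    "ManDis": "Manage distress or upsetting topics sensitively",
    "ManConf": "Manage confusion or memory problems sensitively, reassure",
    "AttOrient": "Explicitly orient the partner's attention",
    "ReduceChoice": "Reduce an alternatives question to a single yes/no choice",
}

_NON_FACILITATIVE: dict[str, str] = {
    "NoTime": "Insufficient time left for the partner to respond",
    "NoActListen": "Partner meaning ignored, disregarded or overridden",
    "NoManConf": "Argue/contradict or echo a memory problem instead of reassuring",
    "NoClearRef": "Expression used without a clear referent",
    "MultQ": "Multiple questions asking different information with no time between",
    "NoRep": "No repeat or rephrase offered after trouble",
    "NoClearTopic": "Topic not made clear when introduced or changed",
    "RemQ": "Follow-up 'do you remember/recall/know' question",
    "NoWorkOut": "No attempt to work out what the partner is trying to say",
    "SelfRep": "Repeat own utterance with neither pause nor trouble in between",
    "TestQ": "Ask for already-known information to probe memory",
    "TalkDown": "Condescending register (babytalk / elderspeak)",
    "NoFamWord": "Use of a low-frequency / difficult word",
}

# Alternate spellings seen in coded transcripts, normalised to registry labels.
CODE_ALIASES: dict[str, str] = {"MixedQSupport": "MixedQ"}

#: Parenthetical notations recognised by default.  The full notation
#: vocabulary of a coding scheme is configurable; unknown parentheticals are
#: still stripped from the spoken content and recorded verbatim.
DEFAULT_NOTATIONS = frozenset(
    {
        "spause",
        "mpause",
        "lpause",
        "xlpause",
        "laugh",
        "laughs",
        "affirm",
        "unintelligible",
        "interruption",
    }
)


def default_registry() -> dict[str, BehaviourCode]:
    """Return the default behaviour-code registry (22 facilitative + 13 non-facilitative)."""
    reg = {
        label: BehaviourCode(label, "facilitative", desc)
        for label, desc in _FACILITATIVE.items()
    }
    reg.update(
        {
            label: BehaviourCode(label, "non-facilitative", desc)
            for label, desc in _NON_FACILITATIVE.items()
        }
    )
    return reg


@dataclass(frozen=True)
class Utterance:
    """One speaker turn.

    ``raw_text`` is the verbatim transcript line including annotations;
    ``clean_text`` contains the spoken words only, with bracketed codes,
    parenthetical notations and reconstruction fragments removed.
    """

    index: int
    speaker: str
    raw_text: str
    clean_text: str
    behaviour_codes: frozenset[str] = frozenset()
    notations: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Conversation:
    """An ordered dyadic conversation between two speaker channels."""

    id: str
    utterances: tuple[Utterance, ...]
    channels: tuple[str, str]

    def __len__(self) -> int:
        return len(self.utterances)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`TranscriptError` on failure."""
        for i, utt in enumerate(self.utterances):
            if utt.index != i:
                raise TranscriptError(
                    f"utterance indices must be consecutive from 0; "
                    f"found index {utt.index} at position {i}"
                )
            if utt.speaker not in self.channels:
                raise DyadViolationError(
                    f"utterance {i} speaker {utt.speaker!r} not in channels {self.channels}"
                )
        spoken = {u.speaker for u in self.utterances}
        if self.utterances and spoken != set(self.channels):
            raise DyadViolationError(
                f"valid dyad requires at least one utterance per channel; "
                f"only {sorted(spoken)} spoke"
            )


@dataclass
class ParserConfig:
    """Options controlling transcript parsing.

    ``strict`` makes unknown bracketed codes an error instead of a warning;
    ``drop_interruptions`` removes rows that consist solely of an
    ``(interruption)`` marker (excluded from analysis); ``channels`` pins the
    two speaker roles rather than inferring them from first appearance.
    """

    channels: tuple[str, str] | None = None
    strict: bool = False
    delimiter: str = ","
    drop_interruptions: bool = True
    registry: Mapping[str, BehaviourCode] = field(default_factory=default_registry)
    notations: frozenset[str] = DEFAULT_NOTATIONS
    aliases: Mapping[str, str] = field(default_factory=lambda: dict(CODE_ALIASES))


_BRACKET_RE = re.compile(r"\[([^\[\]]*)\]")
_PAREN_RE = re.compile(r"\(([^()]*)\)")
_CODE_SHAPE_RE = re.compile(r"[A-Z][A-Za-z0-9]*")
_SPACE_BEFORE_PUNCT_RE = re.compile(r"\s+([.,!?;:])")


def extract_annotations(
    raw_text: str,
    registry: Mapping[str, BehaviourCode] | None = None,
    notations: frozenset[str] = DEFAULT_NOTATIONS,
    strict: bool = False,
    aliases: Mapping[str, str] | None = None,
    _context: str = "",
) -> tuple[str, frozenset[str], frozenset[str]]:
    """Split a raw utterance line into spoken text, behaviour codes and notations.

    Bracketed spans shaped like code identifiers (``[ActListen]``) are looked
    up in ``registry``; other bracketed spans (reconstruction fragments such
    as ``[wh-]``) are removed silently.  All parenthetical spans are removed;
    their contents are reported as notations.  Unbalanced brackets are logged
    and left as literal text.

    Returns ``(clean_text, behaviour_codes, notations)``.
    """
    if registry is None:
        registry = default_registry()
    if aliases is None:
        aliases = CODE_ALIASES

    codes: set[str] = set()
    found_notations: set[str] = set()

    def _bracket(match: re.Match[str]) -> str:
        span = match.group(1).strip()
        if _CODE_SHAPE_RE.fullmatch(span):
            label = aliases.get(span, span)
            if label in registry:
                codes.add(label)
            elif strict:
                raise UnknownCodeError(
                    f"unknown behaviour code {span!r}{_context}"
                )
            else:
                logger.warning("keeping unregistered behaviour code %r%s", span, _context)
                codes.add(label)
        # anything else (fragments like [wh-], [I-I-I]) is dropped
        return " "

    def _paren(match: re.Match[str]) -> str:
        span = match.group(1).strip()
        if span:
            found_notations.add(span.lower() if span.lower() in notations else span)
        return " "

    text = _BRACKET_RE.sub(_bracket, raw_text)
    text = _PAREN_RE.sub(_paren, text)
    if "[" in text or "]" in text or "(" in text or ")" in text:
        logger.warning("unbalanced annotation delimiters left as literal text%s", _context)

    text = _SPACE_BEFORE_PUNCT_RE.sub(r"\1", text)
    text = " ".join(text.split())
    return text, frozenset(codes), frozenset(found_notations)


def _is_header(row: list[str]) -> bool:
    return len(row) >= 2 and row[0].strip().lower() == "speaker" and row[1].strip().lower() in (
        "text",
        "raw_text",
    )


def parse_transcript(
    stream: TextIO | str | Path | Iterable[str],
    config: ParserConfig | None = None,
    conversation_id: str = "conversation",
) -> Conversation:
    """Parse a two-column delimited transcript into a :class:`Conversation`.

    ``stream`` may be an open text handle, a path, or an iterable of lines.
    Rows that consist solely of an ``(interruption)`` marker are dropped when
    ``config.drop_interruptions`` is set; remaining utterances are re-indexed
    consecutively from 0 so their relative order is preserved.
    """
    cfg = config or ParserConfig()

    close_after = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "r", encoding="utf-8", newline="")
        close_after = True
    try:
        reader = csv.reader(stream, delimiter=cfg.delimiter)
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    finally:
        if close_after:
            stream.close()  # type: ignore[union-attr]

    if rows and _is_header(rows[0]):
        rows = rows[1:]
    if not rows:
        raise EmptyTranscriptError(f"transcript {conversation_id!r} contains no utterances")

    speakers_seen: list[str] = []
    utterances: list[Utterance] = []
    for row_no, row in enumerate(rows, start=1):
        if len(row) < 2:
            raise TranscriptError(
                f"row {row_no}: expected (speaker, text) columns, got {row!r}"
            )
        speaker = row[0].strip()
        raw_text = row[1]
        if speaker not in speakers_seen:
            speakers_seen.append(speaker)
        clean, codes, nots = extract_annotations(
            raw_text,
            registry=cfg.registry,
            notations=cfg.notations,
            strict=cfg.strict,
            aliases=cfg.aliases,
            _context=f" (row {row_no} of {conversation_id!r})",
        )
        if cfg.drop_interruptions and "interruption" in nots and not clean and not codes:
            logger.debug("dropping interruption-only row %d of %s", row_no, conversation_id)
            continue
        utterances.append(
            Utterance(
                index=len(utterances),
                speaker=speaker,
                raw_text=raw_text,
                clean_text=clean,
                behaviour_codes=codes,
                notations=nots,
            )
        )

    if len(speakers_seen) > 2:
        raise DyadViolationError(
            f"dyadic transcript expected exactly two speakers, found "
            f"{len(speakers_seen)}: {speakers_seen}"
        )
    if cfg.channels is not None:
        channels = cfg.channels
        unknown = [s for s in speakers_seen if s not in channels]
        if unknown:
            raise DyadViolationError(
                f"speakers {unknown} not in declared channels {channels}"
            )
    else:
        if len(speakers_seen) < 2:
            raise DyadViolationError(
                f"dyadic transcript expected two speakers, found only {speakers_seen}; "
                "declare channels explicitly to accept a one-sided transcript"
            )
        channels = (speakers_seen[0], speakers_seen[1])

    return Conversation(id=conversation_id, utterances=tuple(utterances), channels=channels)


def write_conversation(conv: Conversation, stream: TextIO | str | Path) -> None:
    """Write a conversation as ``speaker,text`` CSV (RFC-4180 quoting).

    Raw text (including annotations) is written, so
    ``parse_transcript(write_conversation(c)) == c`` for any parsed
    conversation.
    """
    close_after = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "w", encoding="utf-8", newline="")
        close_after = True
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(["speaker", "text"])
        for utt in conv.utterances:
            writer.writerow([utt.speaker, utt.raw_text])
    finally:
        if close_after:
            stream.close()  # type: ignore[union-attr]


def conversation_to_csv(conv: Conversation) -> str:
    """Return the CSV serialisation of ``conv`` as a string."""
    buf = io.StringIO()
    write_conversation(conv, buf)
    return buf.getvalue()
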