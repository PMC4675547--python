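"""Binary content-engagement labels and the corpus-level turn table.

A turn "engages" in a given direction and range when the corresponding
other-recurrence metric is positive.  Because short-term recurrence is also
counted inside the medium and long windows, the longer ranges are labelled
*only in isolation*: medium is Yes only when short is No, and long is Yes
only when both short and medium are No.  Each carer turn thus carries at most
one Yes per direction, locating the engagement on a single time scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .recurrence_engine import METRIC_COLUMNS
from .transcript_io import Conversation

__all__ = [
    "RECURRENCE_EPS",
    "EngagementLabels",
    "TurnRecord",
    "binarize",
    "label_conversation",
    "build_turn_table",
    "records_to_frame",
]

#: Threshold above which a recurrence metric counts as "present".  Similarities
#: are exact rationals of small integers, so anything this small is
#: floating-point representation noise, not recurrence.
RECURRENCE_EPS = 1e-12

RANGES = ("short", "medium", "long")
DIRECTIONS = ("forward", "backward")


@dataclass(frozen=True)
class EngagementLabels:
    """Six binary labels per turn: direction (forward/backward) x range."""

    forward_short: bool
    forward_medium: bool
    forward_long: bool
    backward_short: bool
    backward_medium: bool
    backward_long: bool

    def get(self, direction: str, range_: str) -> bool:
        return getattr(self, f"{direction}_{range_}")


@dataclass(frozen=True)
class TurnRecord:
    """One analysed carer turn with its behaviour codes and engagement labels."""

    conversation_id: str
    index: int
    speaker: str
    behaviour_codes: frozenset[str]
    labels: EngagementLabels


def binarize(short: float, medium: float, long: float) -> tuple[bool, bool, bool]:
    """Convert one direction's (short, medium, long) metrics to isolated labels.

    short  = Yes iff the short metric is positive;
    medium = Yes iff the medium metric is positive and short is No;
    long   = Yes iff the long metric is positive and both others are No.
    """
    for name, value in (("short", short), ("medium", medium), ("long", long)):
        if value < 0:
            raise ValueError(f"{name} metric must be non-negative, got {value}")
    s = short > RECURRENCE_EPS
    m = medium > RECURRENCE_EPS and not s
    l = long > RECURRENCE_EPS and not s and not m
    return s, m, l


def label_metrics_row(row: pd.Series) -> EngagementLabels:
    """Label one turn's metric row (uses the ``other_*`` columns)."""
    fs, fm, fl = binarize(
        row["other_forward_short"], row["other_forward_medium"], row["other_forward_long"]
    )
    bs, bm, bl = binarize(
        row["other_backward_short"], row["other_backward_medium"], row["other_backward_long"]
    )
    return EngagementLabels(fs, fm, fl, bs, bm, bl)


def label_conversation(
    conv: Conversation,
    metrics: pd.DataFrame,
    carer_channel: str = "CS",
    include_partner: bool = False,
) -> list[TurnRecord]:
    """Label one conversation's turns and return its analysis records.

    By default only carer-channel turns yield records — the behaviour codes
    sit on carer turns and the analyses are carer-anchored.  Partner turns can
    be retained for diagnostics with ``include_partner``.
    """
    if len(metrics) != len(conv):
        raise ValueError(
            f"metrics/conversation misalignment for {conv.id!r}: "
            f"{len(metrics)} metric rows vs {len(conv)} turns"
        )
    missing = [c for c in METRIC_COLUMNS[:6] if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics frame lacks columns {missing}")

    records: list[TurnRecord] = []
    for utt, (_, row) in zip(conv.utterances, metrics.iterrows()):
        if utt.speaker != carer_channel and not include_partner:
            continue
        records.append(
            TurnRecord(
                conversation_id=conv.id,
                index=utt.index,
                speaker=utt.speaker,
                behaviour_codes=utt.behaviour_codes,
                labels=label_metrics_row(row),
            )
        )
    return records


def build_turn_table(
    corpus: Sequence[Conversation],
    metrics: Sequence[pd.DataFrame],
    carer_channel: str = "CS",
    include_partner: bool = False,
) -> list[TurnRecord]:
    """Collate per-conversation labels into the single corpus-level turn table.

    ``metrics[i]`` must be the primitive-metrics frame of ``corpus[i]``,
    computed with that conversation's own vocabulary.
    """
    if len(corpus) != len(metrics):
        raise ValueError(
            f"corpus/metrics misalignment: {len(corpus)} conversations vs "
            f"{len(metrics)} metric frames"
        )
    records: list[TurnRecord] = []
    for conv, frame in zip(corpus, metrics):
        records.extend(
            label_conversation(
                conv, frame, carer_channel=carer_channel, include_partner=include_partner
            )
        )
    return records


def records_to_frame(records: Iterable[TurnRecord]) -> pd.DataFrame:
    """Export turn records as a flat Y/N table."""
    rows = []
    for r in records:
        rows.append(
            {
                "conversation_id": r.conversation_id,
                "index": r.index,
                "speaker": r.speaker,
                "codes": ";".join(sorted(r.behaviour_codes)),
                "fwd_short": "Y" if r.labels.forward_short else "N",
                "fwd_med": "Y" if r.labels.forward_medium else "N",
                "fwd_long": "Y" if r.labels.forward_long else "N",
                "bwd_short": "Y" if r.labels.backward_short else "N",
                "bwd_med": "Y" if r.labels.backward_medium else "N",
                "bwd_long": "Y" if r.labels.backward_long else "N",
            }
        )
    columns = [
        "conversation_id",
        "index",
        "speaker",
        "codes",
        "fwd_short",
        "fwd_med",
        "fwd_long",
        "bwd_short",
        "bwd_med",
        "bwd_long",
    ]
    return pd.DataFrame(rows, columns=columns)


def frame_to_records(frame: pd.DataFrame) -> list[TurnRecord]:
    """Inverse of :func:`records_to_frame` (used by the CLI pipeline)."""
    records = []
    for _, row in frame.iterrows():
        codes = frozenset(c for c in str(row["codes"]).split(";") if c) if pd.notna(
            row["codes"]
        ) else frozenset()
        records.append(
            TurnRecord(
                conversation_id=str(row["conversation_id"]),
                index=int(row["index"]),
                speaker=str(row["speaker"]),
                behaviour_codes=codes,
                labels=EngagementLabels(
                    *(row[c] == "Y" for c in (
                        "fwd_short", "fwd_med", "fwd_long",
                        "bwd_short", "bwd_med", "bwd_long",
                    ))
                ),
            )
        )
    return records
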