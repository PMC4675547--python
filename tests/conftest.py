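"""Shared fixtures: the packaged example dialogue and small helpers."""

from __future__ import annotations

import io

import pytest

import convrecur as cr


@pytest.fixture(scope="session")
def example_conversation() -> cr.Conversation:
    """The packaged 14-turn CS/PWD example dialogue."""
    return cr.load_example_conversation()


@pytest.fixture(scope="session")
def example_metrics(example_conversation):
    vocab = cr.build_vocabulary(example_conversation)
    return cr.primitive_metrics(cr.recurrence_matrix(example_conversation, vocab))


def parse_text(text: str, **kwargs) -> cr.Conversation:
    """Parse a transcript given inline as CSV text."""
    return cr.parse_transcript(io.StringIO(text), **kwargs)
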