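"""Tokenisation, vocabulary, similarity and the primitive-metric engine."""

from __future__ import annotations

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import convrecur as cr
from convrecur.recurrence_engine import METRIC_COLUMNS, TurnVector
from convrecur.transcript_io import Conversation, Utterance


def make_conversation(texts, speakers=None, conv_id="t"):
    """Build a conversation directly from clean texts (no annotations)."""
    if speakers is None:
        speakers = ["CS" if i % 2 else "PWD" for i in range(len(texts))]
    utts = tuple(
        Utterance(index=i, speaker=s, raw_text=t, clean_text=t)
        for i, (s, t) in enumerate(zip(speakers, texts))
    )
    return Conversation(id=conv_id, utterances=utts, channels=("PWD", "CS"))


# ---------------------------------------------------------------------------
# independent brute-force oracle


def oracle_metrics(conv, vocab):
    """Exhaustive re-implementation of the twelve metrics from first principles."""
    token_sets = [
        {t for t in cr.tokenize(u.clean_text) if t in set(vocab.terms)}
        for u in conv.utterances
    ]

    def sim(i, j):
        m, n = len(token_sets[i]), len(token_sets[j])
        if m == 0 or n == 0:
            return 0.0
        return len(token_sets[i] & token_sets[j]) / np.sqrt(m * n)

    n = len(conv)
    speakers = [u.speaker for u in conv.utterances]
    rows = []
    for t in range(n):
        row = {}
        for kind in ("other", "self"):
            def qualifies(u):
                same = speakers[u] == speakers[t]
                return (not same) if kind == "other" else same

            for direction in ("forward", "backward"):
                if direction == "forward":
                    adjacent = t + 1 if t + 1 < n else None
                    medium_idx = [u for u in range(t + 1, min(n, t + 11)) if qualifies(u)]
                    long_idx = [u for u in range(t + 1, n) if qualifies(u)]
                else:
                    adjacent = t - 1 if t - 1 >= 0 else None
                    medium_idx = [u for u in range(max(0, t - 10), t) if qualifies(u)]
                    long_idx = [u for u in range(0, t) if qualifies(u)]
                short = sim(t, adjacent) if adjacent is not None and qualifies(adjacent) else 0.0
                med_vals = np.array([sim(t, u) for u in medium_idx])
                long_vals = np.array([sim(t, u) for u in long_idx])
                row[f"{kind}_{direction}_short"] = short
                row[f"{kind}_{direction}_medium"] = (
                    float(med_vals.sum() / med_vals.size) if med_vals.size else 0.0
                )
                row[f"{kind}_{direction}_long"] = (
                    float(long_vals.sum() / long_vals.size) if long_vals.size else 0.0
                )
        rows.append(row)
    return rows


def random_conversation(rng, max_turns=12, max_vocab=10):
    n = int(rng.integers(2, max_turns + 1))
    vocab_words = [f"zeta{k}" for k in range(max_vocab)]
    # allow occasional consecutive same-speaker turns
    speakers = ["PWD"]
    for _ in range(n - 1):
        speakers.append(
            speakers[-1] if rng.random() < 0.15 else ("CS" if speakers[-1] == "PWD" else "PWD")
        )
    texts = []
    for _ in range(n):
        k = int(rng.integers(0, 5))
        words = list(rng.choice(vocab_words, size=k, replace=False)) if k else []
        texts.append(" ".join(words))
    return make_conversation(texts, speakers)


# ---------------------------------------------------------------------------


class TestTokenize:
    @pytest.mark.parametrize(
        "text, tokens",
        [
            ("No they don't bark so much.", ["no", "they", "don't", "bark", "so", "much"]),
            ("", []),
            ("they- you- you could pet them", ["they", "you", "you", "could", "pet", "them"]),
            ("It’s hard work, naturally.", ["it's", "hard", "work", "naturally"]),
        ],
    )
    def test_examples(self, text, tokens):
        assert cr.tokenize(text) == tokens


class TestVocabulary:
    def test_cap_not_binding(self):
        conv = make_conversation(["alpha beta gamma", "beta delta"])
        vocab = cr.build_vocabulary(conv, stopwords=frozenset())
        assert set(vocab.terms) == {"alpha", "beta", "gamma", "delta"}
        assert vocab.terms[0] == "beta"  # most frequent first

    def test_example_vocabulary_contains_recurring_terms(self, example_conversation):
        vocab = cr.build_vocabulary(example_conversation)
        assert "yelp" in vocab.terms and "bark" in vocab.terms
        assert not set(vocab.terms) & cr.default_stopwords()

    def test_tie_break_truncation_matches_counter_oracle(self):
        # 300 distinct equally frequent words: the first 200 by occurrence stay
        words = [f"word{i:03d}" for i in range(300)]
        conv = make_conversation([" ".join(words[i : i + 10]) for i in range(0, 300, 10)])
        vocab = cr.build_vocabulary(conv, stopwords=frozenset(), max_terms=200)
        counter = collections.Counter(
            t for u in conv.utterances for t in cr.tokenize(u.clean_text)
        )
        assert all(counter[w] == 1 for w in words)
        assert list(vocab.terms) == words[:200]

    def test_all_stopword_conversation_is_valid_and_silent(self):
        conv = make_conversation(["yeah right", "no no like"])
        vocab = cr.build_vocabulary(conv)
        assert len(vocab) == 0
        m = cr.recurrence_matrix(conv, vocab)
        assert not m.sim.any()

    def test_stopword_appendix_leaves_metrics_unchanged(self, example_conversation):
        base = cr.primitive_metrics(
            cr.recurrence_matrix(
                example_conversation, cr.build_vocabulary(example_conversation)
            )
        )
        padded = make_conversation(
            [u.clean_text + " yeah right hmm no like" for u in example_conversation.utterances],
            [u.speaker for u in example_conversation.utterances],
        )
        after = cr.primitive_metrics(
            cr.recurrence_matrix(padded, cr.build_vocabulary(padded))
        )
        assert np.allclose(base.to_numpy(), after.to_numpy())


class TestSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0, 0], [1, 0, 0], 1.0),
            ([1, 1, 0], [0, 0, 1], 0.0),
            ([1, 1, 1, 1, 0, 0], [1, 0, 0, 0, 1, 0], 1 / np.sqrt(8)),  # m=4, n=2, shared=1
            ([1, 1, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0], 2 / np.sqrt(8)),  # m=2, n=4, shared=2
        ],
    )
    def test_examples(self, a, b, expected):
        got = cr.similarity(np.array(a), np.array(b))
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == cr.similarity(np.array(b), np.array(a))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cr.similarity(np.array([1, 0]), np.array([1, 0, 1]))

    def test_turn_vector_validates_binary(self):
        with pytest.raises(ValueError):
            TurnVector(0, np.array([0, 2, 1]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_bounds_and_symmetry(self, data):
        dim = data.draw(st.integers(1, 12))
        bits = st.lists(st.integers(0, 1), min_size=dim, max_size=dim)
        a = np.array(data.draw(bits))
        b = np.array(data.draw(bits))
        s = cr.similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == cr.similarity(b, a)
        if not (a & b).any():
            assert s == 0.0

    def test_monotone_in_shared_terms(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            dim = 10
            a = rng.integers(0, 2, dim)
            b = rng.integers(0, 2, dim)
            free = np.flatnonzero((a == 0) & (b == 0))
            if free.size == 0:
                continue
            j = int(free[0])
            a2, b2 = a.copy(), b.copy()
            a2[j] = b2[j] = 1
            assert cr.similarity(a2, b2) >= cr.similarity(a, b)


class TestRecurrenceMatrix:
    def test_single_turn(self):
        conv = make_conversation(["alpha"], ["PWD"])
        m = cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
        assert m.sim.shape == (1, 1) and m.sim[0, 0] == 1.0

    def test_disjoint_turns_off_diagonal_zero(self):
        conv = make_conversation(["alpha beta", "gamma delta"])
        m = cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
        assert m.sim[0, 1] == 0.0 and m.sim[1, 0] == 0.0
        assert m.sim[0, 0] == m.sim[1, 1] == 1.0

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            conv = random_conversation(rng)
            m = cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
            assert np.array_equal(m.sim, m.sim.T)
            assert (m.sim >= 0).all() and (m.sim <= 1).all()

    def test_contentless_turn_has_zero_diagonal(self):
        conv = make_conversation(["alpha", ""], ["PWD", "CS"])
        m = cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
        assert m.sim[1, 1] == 0.0


class TestPrimitiveMetrics:
    def test_no_shared_terms_all_zero(self):
        conv = make_conversation(["alpha", "beta", "gamma", "delta"])
        met = cr.primitive_metrics(
            cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
        )
        assert not met.to_numpy().any()

    def test_single_adjacent_recurrence_window_division(self):
        # one shared term between turns 0 and 1 in a 12-turn conversation:
        # forward short = s; forward medium = s / (# partner turns in window)
        texts = ["alpha", "alpha"] + ["x%d" % i for i in range(10)]
        conv = make_conversation(texts)
        met = cr.primitive_metrics(
            cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
        )
        s = met.loc[0, "other_forward_short"]
        assert s == 1.0
        assert met.loc[0, "other_forward_medium"] == pytest.approx(s / 5)  # turns 1,3,5,7,9
        assert met.loc[0, "other_forward_long"] == pytest.approx(s / 6)  # turns 1..11 odd

    def test_last_turn_has_zero_forward_metrics(self):
        rng = np.random.default_rng(3)
        conv = random_conversation(rng)
        met = cr.primitive_metrics(
            cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
        )
        last = met.iloc[-1]
        for col in METRIC_COLUMNS:
            if "forward" in col:
                assert last[col] == 0.0

    def test_medium_equals_long_in_short_conversations(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            conv = random_conversation(rng, max_turns=11)
            met = cr.primitive_metrics(
                cr.recurrence_matrix(conv, cr.build_vocabulary(conv, stopwords=frozenset()))
            )
            assert np.allclose(met["other_forward_medium"], met["other_forward_long"]) or len(
                conv
            ) > 11
            assert np.allclose(met["other_backward_medium"], met["other_backward_long"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            conv = random_conversation(rng)
            vocab = cr.build_vocabulary(conv, stopwords=frozenset())
            met = cr.primitive_metrics(cr.recurrence_matrix(conv, vocab))
            expected = oracle_metrics(conv, vocab)
            for t, row in enumerate(expected):
                for col in METRIC_COLUMNS:
                    assert met.loc[t, col] == row[col], (t, col, conv.id)


class TestMetricsFrameAndPlot:
    def test_metrics_frame_schema(self, example_conversation):
        frame = cr.metrics_frame(example_conversation)
        assert list(frame.columns[:4]) == ["conversation_id", "index", "speaker", "text"]
        assert list(frame.columns[4:16]) == METRIC_COLUMNS
        assert frame.loc[3, "behaviour_codes"] == "ActListen"

    def test_plot_smoke(self, tmp_path, example_conversation):
        vocab = cr.build_vocabulary(example_conversation)
        m = cr.recurrence_matrix(example_conversation, vocab)
        out = tmp_path / "plot.svg"
        cr.render_recurrence_plot(m, example_conversation, out)
        assert out.exists() and out.stat().st_size > 0

    def test_plot_empty_conversation(self, tmp_path):
        conv = Conversation(id="empty", utterances=(), channels=("PWD", "CS"))
        m = cr.recurrence_matrix(conv, cr.build_vocabulary(conv))
        out = tmp_path / "empty.png"
        cr.render_recurrence_plot(m, conv, out)
        assert out.exists()
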