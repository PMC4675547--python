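# Methods

`convrecur` implements a hybrid discourse-analysis pipeline for dyadic
conversations between a care staff member (CS) and a person with dementia
(PWD): manual communication-behaviour codes embedded in the transcript are
related to *content-based conversational engagement*, an automated,
term-recurrence measure of whether the speakers pick up each other's words.
This note records the model, its assumptions, the parameters that matter,
and the choices made where the design was genuinely open.

## Transcript model

A transcript is an ordered list of speaker turns over exactly two channels.
Turn text may carry bracketed behaviour codes (`[ActListen]`) placed by human
coders and parenthetical notations (`(SPause)`, `(laugh)`). Parsing strips
both from the spoken content; codes are validated against a registry of 22
facilitative and 13 non-facilitative behaviours. Open decisions and their
resolutions:

- **Bracketed spans that are not codes.** Reconstruction fragments such as
  `[wh-]` or `[I-I-I]` are removed silently: they are transcription artefacts,
  not speech and not codes. A span is treated as a *code candidate* only when
  it is shaped like an identifier (initial capital, alphanumeric). Unknown
  candidates warn and are kept by default (user-defined schemes are legal);
  `strict` mode raises instead.
- **Interruption rows.** Rows consisting solely of an `(interruption)` marker
  are conversation breaks, not turns, and are dropped; remaining turns are
  re-indexed consecutively so window arithmetic never sees a gap. A row with
  an interruption marker *and* spoken content is a real turn and is kept.
- **Notation-only turns** (a bare `(laugh)`) are kept as turns with empty
  spoken content: turn count drives the window metrics, and minimal turns are
  real conversational moves.
- Codes are matched case-sensitively; `MixedQSupport` is accepted as an alias
  of `MixedQ`.
- Serialisation is `speaker,text` CSV with RFC-4180 quoting; parsing and
  writing are exact inverses on valid conversations (round-trip tested).

## Recurrence model

Per conversation — never pooled across conversations — a vocabulary of
content terms is built: tokens are lowercased, punctuation-stripped words
(contractions intact, false starts reduced to the bare word), stopwords are
removed, and the remaining terms are ranked by descending frequency with ties
broken by first occurrence, truncated to `max_terms` (default **200**).

Each turn becomes a binary term-presence vector, and the similarity of two
turns is the cosine of those binary vectors, `shared / sqrt(m·n)`. This
closed form was chosen because the published example values it must reproduce
are exactly of this shape (0.354 = 1/√8, 0.707 = 2/√8 or 1/√2); frequency
weighting is deliberately absent, since a turn either does or does not supply
a term to the conversation.

The twelve primitive metrics per turn combine three time scales × two
directions × two types:

- **short** — the similarity to the single adjacent turn, 0 when the adjacent
  turn is the wrong type (partner for *other*, same speaker for *self*);
- **medium** — the mean similarity to the qualifying turns within ten turns
  (raw turn distance, both speakers counted toward the distance);
- **long** — the same mean over all remaining turns in that direction.

Means divide by the number of qualifying turns actually present in the
window, so boundary turns average over shorter windows and an empty window
gives 0. The diagonal (a turn with itself) is never included. The published
example table implies the divisor-by-present-turns convention in all rows but
one (a single forward-medium cell implies a divisor of 4 where this model
gives 5); that cell cannot be reconciled with the others under any uniform
convention, and the implementation is pinned instead by an exhaustive
brute-force oracle over random small conversations (exact equality, 500
conversations).

The default stopword list (packaged, one term per line, user-replaceable)
contains English function words, contractions, backchannel forms and the
ambiguous conversational tokens *no, hmm, yeah, right, like*. The exact list
used to produce the published corpus results is unpublished, so desk-scale
reproductions of the example dialogue match its *pattern* of recurrence (which
turn pairs share content) rather than its decimal values, which also depend
on the full conversation the excerpt was drawn from.

## Engagement labels

For each carer turn, the six *other*-metrics are binarised: a metric counts
as present when it exceeds `1e-12` (similarities are exact rationals of small
integers; anything smaller is floating-point noise, and the threshold is not
a tuning parameter). Because short-term recurrence is counted inside the
medium and long windows, the longer ranges are labelled **only in
isolation** — medium requires short absent, long requires both shorter ranges
absent — so each direction carries at most one Yes and exactly one Yes
whenever any other-recurrence exists. Only carer turns enter the analysis
table (behaviour codes exist only there); partner-turn records are available
behind a flag for diagnostics. Self-metrics are computed and exported but
never binarised.

## Association statistics

For each behaviour × engagement dimension, carer turns are cross-tabulated
into a 2×2 table and summarised by the odds ratio `ad/(bc)` with the 95% Wald
interval `exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))` and Wald p-value. The Wald
(not profile-likelihood) interval is used because it reproduces the published
intervals from their printed cells to ±0.001. The default fitting route is a
univariate binomial GLM (logit link) on the aggregated table; with a single
binary predictor the model is saturated, so its exponentiated coefficient
equals the closed form — the two routes are compared to 1e-6 in tests rather
than collapsed into one. Under separation (a zero cell) the logistic MLE does
not exist; the result falls back to the closed-form convention (OR 0 with a
degenerate interval when no exposed turn engaged, ∞ when no exposed turn
failed to) and carries a `separation` flag. No continuity correction is
applied by default; Haldane–Anscombe +0.5 would change published-value
reconstruction and is left to the caller.

Behaviours enter the analysis only when used on at least
`ceil(min_fraction · n_carer_turns)` turns (default 1%; at the published
corpus size of 1,743 carer turns this is 18). Results tables order behaviours
by frequency, mark p < .05/.01/.005 with stars, and perform *separate* tests
per behaviour with no multiplicity correction — matching the analysis design
being reproduced; a Benjamini–Hochberg column is available behind a flag and
clearly additional. Turns are pooled across conversations; within-dyad
clustering is ignored, a known limitation of the per-turn design (a
mixed-effects extension is out of scope).

## Synthetic conversations

The generator emulates the statistical structure the pipeline consumes, not
English syntax or dementia-specific lexical profiles. Defaults mirror the
study-scale corpus: **20** conversations of **~173** alternating turns
(≈3,460 utterances), sparse content terms (mean 3 per turn, truncated
geometric, many short turns), half the tokens filler stopwords, behaviour
codes emitted per carer turn at rates shaped like the published frequency
table (most frequent code ≈31% of carer turns, long sparse tail), baseline
adjacent-turn reuse probability **0.10** (matching the ≈10.5% short-range
engagement base rate of the published corpus) and delayed-reuse probability
0.05.

Design choices that make the generator *analysable*:

- **Fresh terms.** Base content terms are drawn without replacement from a
  conversation-level pool, so two turns share a term only through an explicit
  reuse event. Consequences: with all reuse probabilities 0 every
  other-metric is exactly 0; injected effects are not attenuated by random
  term collisions, so the measured odds ratio converges to the injected odds
  multiplier; and self-recurrence is essentially absent from generated
  corpora (self-metrics are exercised by hand-built fixtures instead). If the
  pool is exhausted the generator falls back to uniform resampling.
- **Reuse events copy one term.** The labels depend only on
  any-shared-term positivity, so copying a single uniformly chosen term from
  the source turn suffices and keeps the event probability interpretable.
- **Windowed effects.** A behaviour effect `(w, window)` multiplies, on the
  odds scale, the probability that the partner reuses the coded turn's
  content within that window: the adjacent turn for `short`, a uniformly
  chosen lag 2–10 for `medium`, beyond 10 for `long`. Medium/long injections
  at random lags make the isolation rule genuinely exercisable.
- **Determinism.** A fixed master seed spawns independent per-conversation
  streams; output is byte-identical across runs and recorded in a manifest
  with the config hash.

What passing the synthetic checks shows — and does not. Null calibration
(~5% of per-behaviour tests significant at α=.05 when no effect is injected)
and CI coverage (≥90% over replicates for an injected multiplier of 4.0 at
~2,000 carer turns) demonstrate that the pipeline is statistically sound on
data matching its assumptions: alternating speakers, independent turns,
single-term reuse. Real conversations violate several of these (topic
persistence, code co-occurrence, within-dyad correlation), so synthetic
calibration does not certify the field results, only the machinery.

## Problem sizes used in the standard checks

The packaged verification suite runs the oracle comparison on 500 random
conversations (≤12 turns, ≤10 terms), the logistic/closed-form comparison on
1,000 random tables, null calibration on 8 corpora of 10×120 turns
(~270 valid tests) and recovery on 100 replicates of 20×200 turns. These
sizes give stable Monte-Carlo estimates (binomial SE ≈1.3% for calibration,
≈2% for coverage) while keeping a full run around a minute on one core.

## Known limitations

- Term-based recurrence only: paraphrase and semantic similarity are
  invisible by design (a concept-grouping mode is explicitly out of scope
  because sparse conversational data cannot support the required language
  model).
- The exact published corpus is not distributable, so corpus-level published
  tables are validated through their printed contingency cells and through
  synthetic parameter recovery, not by re-running the original transcripts.
- Wald intervals misbehave for very sparse cells; rows with zero cells are
  flagged rather than corrected.
- Pooling turns across conversations ignores dyad-level heterogeneity.
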