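# Methods

This note documents the models and procedures implemented in `asrcurate`,
the defaults chosen where a design question was genuinely open, and what the
synthetic-data results do and do not demonstrate.

## Text normalization

All alignment and error computation happens over a restricted character
vocabulary: the 26 basic Latin letters, space, dash and apostrophe — the
output alphabet of the character-level acoustic models this pipeline
targets. Normalization lower-cases (case carries no information for WER),
strips accents by canonical decomposition and removal of combining marks
(é→e, ö→o; no lookup table), maps typographic apostrophes to ASCII, and
replaces every other character with a space before tokenizing on
whitespace. Em and en dashes become spaces rather than hyphens: in interview
transcripts they mark pauses, not compound words; the intra-word ASCII
hyphen is kept. Digits are dropped with a warning by default
(`digit_policy="drop"`) because the target vocabulary has none and no
spell-out convention is defined; `keep_verbatim` retains them for corpora
where that is wrong. Normalization is idempotent, and letters that lack a
combining-mark decomposition (e.g. ø) are treated as punctuation — a known
limitation for Nordic text.

## Local alignment and the similarity gate

A segment hypothesis (< 20 s of speech, so tens of words) is located inside
the full interview transcript by classic Smith–Waterman dynamic programming
over **word tokens**. Word granularity, rather than characters, keeps the
gate strict about *where* in the transcript a segment matches while staying
O(|query|·|transcript|) cheap even for hour-long transcripts; token equality
is exact string equality after normalization.

Scores default to match +2, mismatch −1, gap −1 (a standard parameterization,
exposed in `ScoringScheme`). Similarity is defined as
`MATCH ops / query token count` — zero for an empty query, and exactly 1.0
when every hypothesis word appears in order in the reference. The gate
accepts at `similarity ≥ threshold` (default 0.90); strictly below is
discarded. Determinism is pinned by tie-breaks: among equal-scoring DP cells
the smallest reference end index (then query end index) wins, and traceback
prefers a diagonal step over consuming a reference token over consuming a
query token.

One consequence of score maximality worth knowing: a mismatched *flanking*
word (e.g. a hypothesis whose first word garbles the reference's first word)
is excluded from the optimal local alignment when including it would lower
the score, so the extracted correction span can start one word later than a
human annotator might choose. Gate decisions are unaffected — similarity
counts matches against the full query length either way.

## Edit operations and WER

Word error rate is `(S + I + D) / reference length × 100` from a unit-cost
Levenshtein alignment; it can exceed 100% when insertions dominate, and is
undefined (raises) on an empty reference. Corpus-level WER pools total
errors over total reference words rather than averaging per-segment WERs.
Character-level counts use the space-joined character rendering of the
token sequence.

Among equal-cost alignment paths the traceback prefers substitution, then
deletion, then insertion. The decomposition of a minimal distance into
(S, I, D) is not always unique — `ref "a b"` vs `hyp "b a"` is two
substitutions or a deletion plus an insertion, both cost 2 — so pinning the
tie-break is what makes counts reproducible. Error-type distributions
report each type as a percentage of total errors, pooled per speaker group;
a group with zero errors is flagged rather than divided by zero. Boxplot
statistics use linear-interpolation quartiles and 1.5×IQR whiskers.

## Silence segmentation

Frames of 25 ms at a 10 ms hop are classified silent when their RMS energy
falls below −40 dBFS (a fixed threshold chosen to sit well between typical
recorded-speech levels and recording-noise floors; configurable). Maximal
silent runs at least `min_silence_ms` long (250 ms initially) become cut
regions; detected silences are removed entirely, so segment edges sit at
voiced-region boundaries on the hop grid. Removing the silence, rather than
cutting at its midpoint and keeping the halves, is what lets planted
utterance boundaries be recovered to within one analysis frame; silence
carries no training signal.

Over-long segments are re-split with the minimum silence halved
(250→125→… ms) down to a 15 ms floor. A segment still too long at the floor
is force-split at its lowest-energy frame within the central half of the
segment (so both pieces shrink geometrically and the recursion terminates),
never mid-frame. Segments shorter than 1 s merge into the shorter adjacent
neighbor when the merge respects the 20 s bound — clips that short carry too
little speech to train on. All audio is converted to 16 kHz mono on read.

## The curation loop

Each pass splits every corpus recording, transcribes each segment with the
current backend, aligns, gates, and pairs accepted segments with their
matched transcript slice. Backend failure on one segment marks it `error`
and the pass continues. Accepted pairs are pooled across passes keyed by
(source id, time span), newest correction winning; the pool is what the
backend finetunes on, and its size is the cumulative sample count — which is
therefore non-decreasing even though every pass re-transcribes everything
with the newest model. Validation WER is measured on a fixed held-out set
after every finetune; the loop stops when the improvement over the previous
iteration is ≤ `epsilon_pct` (default 0.0 — any non-decrease, including a
regression, stops), when a pass accepts nothing, or at `max_iterations`
(default 10, a safety cap well above the handful of rounds the method
typically needs).

## Synthetic data and mock backends

The generator plants utterances ("speech" as tone bursts or 300–3400 Hz
band-limited noise at −20 dBFS RMS) over a −55 dBFS Gaussian noise floor,
separated by silences of configurable duration, and records boundaries and
per-utterance texts exactly. Texts draw from a shipped 200-word Dutch-like
vocabulary that is stable under normalization. The defaults (2–8 s
utterances, 300–900 ms silences, 4–14 words per utterance) describe typical
conversational interview pacing. Since the segmenter only ever looks at
frame energy, acoustic realism is deliberately not attempted; what passing
tests show is that the *pipeline logic* — boundary detection, alignment,
gating, bookkeeping — is correct, not that any particular acoustic model
will reach any particular WER on real recordings.

`corrupt_text` injects word-level insertions, deletions and substitutions
at given per-word rates (substitutions always differ from the original
word). Insertion *placement* is constrained for identifiability: an
insertion separated from a deletion by fewer than two matched words would be
re-explained by minimal-edit alignment as a substitution chain (a cheaper or
tie-broken path), so each insertion event relocates to the nearest slot at
least two matched words from every deletion. Event counts are unchanged;
this is the textual analogue of planting silences no shorter than the
detector's minimum, and it is what makes injected rates recoverable to
within a fraction of a percentage point at 10,000 words.

`MockBackend` wraps this corrupter as an ASR backend: it reads the true
text of any segment from the generator's ground truth (utterances
overlapping the segment by at least half), corrupts it at its current word
error rate with a generator keyed by (seed, finetune count, segment
identity) — deterministic for a fixed state — and halves (configurable
`improvement_factor`) its rate on every `finetune` call. The split of the
total rate into insertion/deletion/substitution defaults to 0.2/0.3/0.5, a
plausible word-level ASR error profile. `OracleBackend` is the error-free
special case.

## Problem sizes

Tests and the acceptance script run on deliberately small instances chosen
to exercise every code path with tight statistical margins: 200 random
alignment instances of ≤ 8 tokens against a brute-force oracle, 1,000 random
pairs for the WER identities, 10,000 words for rate recovery (sampling error
≈ 0.3 points), interviews of 6–20 utterances for segmentation, and a
two-interview corpus with a 270-word validation set for the loop. These
sizes make the whole suite run in seconds while keeping each check's
tolerance meaningful.

## Known limitations

- The gate assumes the manual transcript is substantially complete; systematic
  transcript omissions (names redacted, filler words dropped) depress
  similarity and discard genuinely correct segments.
- Energy-threshold silence detection has no notion of babble noise or music;
  an adaptive threshold (10th percentile of frame energies,
  `adaptive_threshold=True`) is available but off by default, and assumes
  the recording actually contains some silence.
- Similarity is word-based; a hypothesis of consistently near-miss spellings
  (common for accented speech) gates to zero even when a character-level
  measure would accept it.
- No affine gap penalties, no fuzzy token matching, no speaker diarization,
  no overlap-speech handling; neural backends (e.g. HuBERT-family acoustic
  models with language-model rescoring) plug in via the backend protocol but
  are not shipped.
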