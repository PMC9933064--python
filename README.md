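# asrcurate

Tools for turning long interview recordings with *untimed* manual transcripts
into curated ASR training corpora, by iterative pseudo-label correction.

## The problem

Qualitative research in long-term care produces hours of recorded interviews
(with residents, family members, care professionals) that are transcribed
verbatim by hand. Those transcripts are full-length text without timestamps,
so they cannot be used directly to finetune a speech recognizer, which needs
short (≤ 20 s) audio segments paired with their exact text. `asrcurate`
implements the curation loop that bridges that gap:

1. **Split** each recording at detected silences (frame RMS below a dBFS
   threshold, minimum silence 250 ms). Any segment still longer than 20 s is
   re-split with the minimum silence halved, down to a floor, then
   force-split at its quietest frame.
2. **Transcribe** every segment with the current ASR model, giving a
   hypothesis *P* per segment.
3. **Align** each hypothesis against the full manual transcript with
   Smith–Waterman local alignment over word tokens (match +2, mismatch −1,
   gap −1). The similarity of a segment is
   `matches / hypothesis-token-count` — 1.0 exactly when every predicted
   word appears, in order, in the transcript.
4. **Gate**: segments with similarity < 90% are discarded; for the rest the
   *matched transcript slice* *P′* (not the ASR output) becomes the training
   label.
5. **Finetune** the model on all accepted pairs, re-measure word error rate
   (WER) on a fixed validation set, and repeat 2–5 until the WER no longer
   improves.

WER is `(S + I + D) / N`: substitutions, insertions and deletions from a
minimal-cost Levenshtein alignment, over the reference length. The same
machinery runs at character level to break total errors into
insertion/substitution/deletion shares per speaker group, plus boxplot
statistics (median, quartiles, 1.5×IQR outliers) of per-segment WERs.

Actual neural acoustic models are behind a small backend protocol
(`transcribe` / `finetune` / `descriptor`); the package ships deterministic
mock backends and a synthetic-interview generator (planted utterances,
silences and corruption rates, all recorded as ground truth) so the entire
pipeline is testable end to end without private interview data or GPUs.

## Worked example

```python
from asrcurate import (
    SynthSpec, generate_interview, MockBackend, curate_pass, iterate,
    IterateConfig, SegmentAudio, normalize, smith_waterman, wer,
)

# A recognizer output vs. the manual transcript: the recognizer restored a
# word the transcriber omitted, and its only real error is a stray leading
# letter — yet naive WER against the manual text is 33%.
hyp = normalize("fthe last question is there anything you want to tell")
ref = normalize("the last—is there something you want to tell")
al = smith_waterman(hyp, ref)
print(f"similarity = {al.similarity:.2f}")   # 0.70 -> discarded at the 90% gate
print(f"word error rate = {wer(ref, hyp):.1f}%")

# Full loop on synthetic interviews with a mock backend whose word error
# rate halves on every finetune.
train = generate_interview(SynthSpec(n_utterances=8, seed=42))
held_out = generate_interview(SynthSpec(n_utterances=6, seed=43))
backend = MockBackend({"train": train, "val": held_out}, word_error_rate=0.3,
                      improvement_factor=0.5, seed=42)

segments = curate_pass(backend, train.audio, train.transcript, source_id="train")
validation = [
    (SegmentAudio("val", b, held_out.audio.slice(b)), t)
    for b, t in zip(held_out.true_boundaries, held_out.true_utterance_texts)
]
records = iterate(backend, [(train.audio, train.transcript, "train")],
                  validation, IterateConfig())
for r in records:
    print(f"iteration {r.iteration_index}: {r.cumulative_accepted_samples:2d} samples, "
          f"validation WER {r.validation_wer_pct:5.1f}%")
```

prints

```
similarity = 0.70
word error rate = 33.3%
iteration 0:  0 samples, validation WER  37.1%
iteration 1:  2 samples, validation WER  12.9%
iteration 2:  6 samples, validation WER  10.0%
iteration 3:  8 samples, validation WER   7.1%
iteration 4:  8 samples, validation WER   1.4%
iteration 5:  8 samples, validation WER   2.9%
```

Iteration 0 is the initial model (no curated samples). Each later row shows
the cumulative accepted segment count and the held-out WER after finetuning
on them: WER falls as curation admits more data, and the loop stops once an
iteration brings no further improvement (here at iteration 5).

The same stages are available from a shell via the `asrcurate` console
script (`synth`, `split`, `curate`, `evaluate`, `iterate` subcommands; see
`asrcurate --help`).

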