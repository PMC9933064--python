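"""The iterative curation loop: transcribe, align, gate, correct, finetune.

One curation pass splits each interview recording at silences, transcribes
every segment with the current ASR backend, locates each hypothesis inside
the full manual transcript by Smith-Waterman alignment, and keeps only
segments whose similarity clears the gate (default 90%). The matched
transcript slice — not the hypothesis — becomes the training label, so the
model learns from human text even where its own output was imperfect.

`iterate` repeats passes, finetuning the backend on all pairs accepted so
far, and stops when the validation WER no longer improves. Validation WER is
corpus-level (total errors over total reference words) on a fixed held-out
set, re-measured after every finetune.

The acoustic model itself is behind the `ASRBackend` protocol; this package
ships deterministic mock backends (a perfect oracle and a corrupting one
whose error rate shrinks on every finetune) that stand in for neural-model
finetuning in tests and simulations.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .audioseg import AudioSignal, SegmenterConfig, TimeSpan, split_recursive
from .metrics import corpus_wer
from .seqalign import ScoringScheme, DEFAULT_SCORING, extract_correction, gate, smith_waterman
from .synthdata import DEFAULT_VOCABULARY, SynthInterview, corrupt_text
from .textnorm import NormalizedText, normalize

__all__ = [
    "SegmentAudio",
    "ASRBackend",
    "SegmentStatus",
    "Segment",
    "IterationRecord",
    "curate_pass",
    "iterate",
    "make_mock_backend",
    "OracleBackend",
    "MockBackend",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentAudio:
    """A cut of a source recording handed to the ASR backend."""

    source_id: str
    span: TimeSpan
    audio: AudioSignal


@runtime_checkable
class ASRBackend(Protocol):
    """Contract any acoustic-model backend must satisfy.

    ``transcribe`` must be deterministic for a fixed backend state and input
    (backends pin their own seeds). ``finetune`` consumes accepted
    (segment audio, corrected text) pairs and updates the backend state.
    ``descriptor`` identifies the state, e.g. for checkpoint logs.
    """

    def transcribe(self, segment: SegmentAudio) -> str: ...

    def finetune(self, pairs: Sequence[tuple[SegmentAudio, NormalizedText]]) -> None: ...

    @property
    def descriptor(self) -> str: ...


class SegmentStatus(str, Enum):
    ACCEPTED = "accepted"
    DISCARDED = "discarded"
    ERROR = "error"


@dataclass(frozen=True)
class Segment:
    """One audio cut with its hypothesis, similarity, and curation outcome.

    ``correction`` is the transcript slice adopted as the training label;
    present iff the segment was accepted.
    """

    source_id: str
    span: TimeSpan
    hypothesis: NormalizedText
    similarity: float
    status: SegmentStatus
    correction: NormalizedText | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        if (self.status is SegmentStatus.ACCEPTED) != (self.correction is not None):
            raise ValueError("correction must be present iff segment is accepted")


@dataclass(frozen=True)
class IterationRecord:
    """One row of the iteration log: cumulative accepted pairs and validation WER."""

    iteration_index: int
    cumulative_accepted_samples: int
    validation_wer_pct: float
    stop_reason: str | None = None


def curate_pass(
    backend: ASRBackend,
    audio: AudioSignal,
    transcript: NormalizedText,
    seg_config: SegmenterConfig = SegmenterConfig(),
    threshold: float = 0.9,
    *,
    source_id: str = "audio",
    scoring: ScoringScheme = DEFAULT_SCORING,
    group_label: str | None = None,
) -> list[Segment]:
    """Split, transcribe, align and gate one recording against its transcript.

    A backend failure on a segment marks that segment ``error`` and the pass
    continues. An empty transcript yields no segments (with a warning): there
    is nothing to align against.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if len(transcript) == 0:
        logger.warning("empty transcript for %s: no segments curated", source_id)
        return []
    segments: list[Segment] = []
    for span in split_recursive(audio, seg_config):
        seg_audio = SegmentAudio(source_id=source_id, span=span, audio=audio.slice(span))
        try:
            raw = backend.transcribe(seg_audio)
        except Exception:
            logger.exception("backend failed on %s %s", source_id, span)
            segments.append(
                Segment(source_id, span, NormalizedText(()), 0.0, SegmentStatus.ERROR, group_label=group_label)
            )
            continue
        hypothesis = normalize(raw)
        alignment = smith_waterman(hypothesis, transcript, scoring)
        if gate(alignment, threshold):
            segments.append(
                Segment(
                    source_id,
                    span,
                    hypothesis,
                    alignment.similarity,
                    SegmentStatus.ACCEPTED,
                    correction=extract_correction(alignment, transcript),
                    group_label=group_label,
                )
            )
        else:
            segments.append(
                Segment(source_id, span, hypothesis, alignment.similarity, SegmentStatus.DISCARDED, group_label=group_label)
            )
    return segments


@dataclass
class IterateConfig:
    """Loop controls: plateau epsilon (percentage points) and iteration cap."""

    threshold: float = 0.9
    epsilon_pct: float = 0.0
    max_iterations: int = 10
    seg_config: SegmenterConfig = field(default_factory=SegmenterConfig)
    scoring: ScoringScheme = DEFAULT_SCORING


def _validation_wer(
    backend: ASRBackend,
    validation_set: Sequence[tuple[SegmentAudio, NormalizedText]],
) -> float:
    pairs = []
    for seg_audio, reference in validation_set:
        hyp = normalize(backend.transcribe(seg_audio))
        pairs.append((reference, hyp))
    return corpus_wer(pairs)


def iterate(
    initial_backend: ASRBackend,
    corpus: Sequence[tuple[AudioSignal, NormalizedText, str]],
    validation_set: Sequence[tuple[SegmentAudio, NormalizedText]],
    config: IterateConfig = IterateConfig(),
) -> list[IterationRecord]:
    """Run curation passes and finetunes until the validation WER plateaus.

    Iteration 0 records the initial backend's validation WER with zero
    accepted samples. Each later iteration re-curates the whole corpus with
    the newest backend, finetunes on every pair accepted so far (pairs are
    pooled across passes keyed by segment identity, newest correction wins),
    and re-measures validation WER. Stops when the WER fails to improve by
    more than ``epsilon_pct`` (also on increase), when a pass accepts
    nothing, or at ``max_iterations``.
    """
    if not validation_set:
        raise ValueError("validation set must be non-empty")
    if config.max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")

    backend = initial_backend
    records = [
        IterationRecord(0, 0, _validation_wer(backend, validation_set))
    ]
    pool: dict[tuple[str, TimeSpan], tuple[SegmentAudio, NormalizedText]] = {}

    for it in range(1, config.max_iterations + 1):
        accepted_this_pass = 0
        for audio, transcript, source_id in corpus:
            for seg in curate_pass(
                backend,
                audio,
                transcript,
                config.seg_config,
                config.threshold,
                source_id=source_id,
                scoring=config.scoring,
            ):
                if seg.status is SegmentStatus.ACCEPTED:
                    assert seg.correction is not None
                    key = (seg.source_id, seg.span)
                    pool[key] = (
                        SegmentAudio(seg.source_id, seg.span, audio.slice(seg.span)),
                        seg.correction,
                    )
                    accepted_this_pass += 1
        if accepted_this_pass == 0:
            logger.info("iteration %d accepted no segments; stopping", it)
            records[-1] = replace(records[-1], stop_reason="no-accepted-samples")
            break
        backend.finetune(list(pool.values()))
        new_wer = _validation_wer(backend, validation_set)
        prev_wer = records[-1].validation_wer_pct
        stop = None
        if prev_wer - new_wer <= config.epsilon_pct:
            stop = "plateau"
        elif it == config.max_iterations:
            stop = "max-iterations"
        records.append(IterationRecord(it, len(pool), new_wer, stop_reason=stop))
        if stop is not None:
            break
    return records


class OracleBackend:
    """Perfect mock: returns the planted true text of any overlapping utterance.

    Built from synthetic interviews; a segment's transcription is the
    concatenated text of every true utterance whose overlap with the segment
    is at least half the utterance (or half the segment, for segments cut
    inside one utterance).
    """

    def __init__(self, interviews: dict[str, SynthInterview]):
        self._interviews = dict(interviews)

    @property
    def descriptor(self) -> str:
        return "oracle"

    def true_text(self, segment: SegmentAudio) -> NormalizedText:
        interview = self._interviews[segment.source_id]
        span = segment.span
        words: list[str] = []
        for bound, text in zip(interview.true_boundaries, interview.true_utterance_texts):
            overlap = min(span.end_s, bound.end_s) - max(span.start_s, bound.start_s)
            if overlap <= 0:
                continue
            if overlap >= 0.5 * min(bound.duration_s, span.duration_s):
                words.extend(text.tokens)
        return NormalizedText(tuple(words))

    def transcribe(self, segment: SegmentAudio) -> str:
        return self.true_text(segment).char_string

    def finetune(self, pairs: Sequence[tuple[SegmentAudio, NormalizedText]]) -> None:
        pass  # already perfect


class MockBackend(OracleBackend):
    """Corrupting mock whose word error rate shrinks on every finetune.

    Words of the true text are independently substituted, deleted or
    inserted-after at rates summing to the current ``word_error_rate``;
    ``finetune`` multiplies that rate by ``improvement_factor``. Output is
    deterministic for a fixed state: the corruption RNG is keyed by
    (seed, finetune count, segment identity).
    """

    def __init__(
        self,
        interviews: dict[str, SynthInterview],
        word_error_rate: float,
        improvement_factor: float = 0.5,
        seed: int = 0,
        error_mix: tuple[float, float, float] = (0.2, 0.3, 0.5),  # (ins, del, sub) shares
        frozen: bool = False,
    ):
        super().__init__(interviews)
        if not 0.0 <= word_error_rate <= 1.0:
            raise ValueError("word_error_rate must be in [0, 1]")
        if not 0.0 < improvement_factor <= 1.0:
            raise ValueError("improvement_factor must be in (0, 1]")
        if abs(sum(error_mix) - 1.0) > 1e-9 or any(m < 0 for m in error_mix):
            raise ValueError("error_mix shares must be non-negative and sum to 1")
        self.word_error_rate = float(word_error_rate)
        self.improvement_factor = float(improvement_factor)
        self.error_mix = error_mix
        self.seed = int(seed)
        self.frozen = frozen
        self._n_finetunes = 0

    @property
    def descriptor(self) -> str:
        return f"mock(rate={self.word_error_rate:.4f},finetunes={self._n_finetunes})"

    def _segment_rng(self, segment: SegmentAudio) -> np.random.Generator:
        key = f"{segment.source_id}|{segment.span.start_s:.4f}|{segment.span.end_s:.4f}"
        digest = zlib.crc32(key.encode())
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, self._n_finetunes, digest])
        )

    def transcribe(self, segment: SegmentAudio) -> str:
        truth = self.true_text(segment)
        ins_share, del_share, sub_share = self.error_mix
        r = self.word_error_rate
        corrupted = corrupt_text(
            truth,
            (r * ins_share, r * del_share, r * sub_share),
            vocabulary=DEFAULT_VOCABULARY,
            seed=self._segment_rng(segment),
        )
        return corrupted.char_string

    def finetune(self, pairs: Sequence[tuple[SegmentAudio, NormalizedText]]) -> None:
        if self.frozen:
            return
        self._n_finetunes += 1
        self.word_error_rate *= self.improvement_factor


def make_mock_backend(
    interviews: dict[str, SynthInterview],
    word_error_rate: float,
    improvement_factor: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> MockBackend:
    """Convenience constructor for the corrupting mock backend."""
    return MockBackend(interviews, word_error_rate, improvement_factor, seed, **kwargs)
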