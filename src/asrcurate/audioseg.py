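"""Silence-based segmentation of long mono recordings.

Interview recordings are hours long, but acoustic-model training needs
segments of at most ~20 s, cut between words rather than through them. The
splitter classifies 25 ms analysis frames (10 ms hop) as silent when their
RMS energy falls below a dBFS threshold, cuts the recording at maximal silent
runs of at least a minimum duration (250 ms initially), and recursively
halves that minimum for any segment still over the length bound. When the
minimum would drop below a floor and a segment is still too long, it is
force-split at its lowest-energy frame, so the length bound always holds.

Segment edges sit on the analysis hop grid at the boundaries of voiced
regions; detected silences are removed, never included in a segment's span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AudioSignal",
    "TimeSpan",
    "SegmenterConfig",
    "InvalidAudioError",
    "detect_silences",
    "split_recursive",
]

INTERNAL_RATE = 16_000


class InvalidAudioError(ValueError):
    """Raised on empty or non-finite sample data."""


@dataclass(frozen=True)
class AudioSignal:
    """Single-channel audio: sample rate in Hz and amplitudes in [-1, 1]."""

    sample_rate: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise InvalidAudioError("AudioSignal is single-channel; got multi-dim samples")
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise InvalidAudioError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def slice(self, span: "TimeSpan") -> "AudioSignal":
        i0 = int(round(span.start_s * self.sample_rate))
        i1 = int(round(span.end_s * self.sample_rate))
        return AudioSignal(self.sample_rate, self.samples[i0:i1])


@dataclass(frozen=True, order=True)
class TimeSpan:
    """Half-open time interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(f"invalid span [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SegmenterConfig:
    """Tunables of the recursive silence splitter.

    ``max_segment_s`` is the training length bound; ``initial_min_silence_ms``
    the first-pass minimum silence duration, halved on recursion down to
    ``silence_floor_ms``. Frames below ``silence_threshold_dbfs`` RMS count
    as silent. Segments shorter than ``min_segment_s`` are merged with a
    neighbor where possible (very short clips carry too little speech to
    train on).
    """

    max_segment_s: float = 20.0
    initial_min_silence_ms: float = 250.0
    silence_floor_ms: float = 15.0
    silence_threshold_dbfs: float = -40.0
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    min_segment_s: float = 1.0
    #: derive the silence threshold from the recording itself (10th
    #: percentile of frame energies) instead of the fixed dBFS value
    adaptive_threshold: bool = False

    def __post_init__(self) -> None:
        if not (self.max_segment_s > self.min_segment_s > 0):
            raise ValueError("need max_segment_s > min_segment_s > 0")
        if not (self.initial_min_silence_ms > self.silence_floor_ms > 0):
            raise ValueError("need initial_min_silence_ms > silence_floor_ms > 0")
        if self.frame_ms <= 0 or self.hop_ms <= 0:
            raise ValueError("frame_ms and hop_ms must be positive")


def _frame_rms_dbfs(audio: AudioSignal, config: SegmenterConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMS in dBFS and frame start times (hop grid).

    A trailing partial frame covers the tail samples, so every sample belongs
    to at least one frame.
    """
    samples = audio.samples
    if len(samples) == 0:
        raise InvalidAudioError("empty audio")
    if not np.all(np.isfinite(samples)):
        raise InvalidAudioError("non-finite sample data")
    sr = audio.sample_rate
    frame = max(1, int(round(config.frame_ms * sr / 1000.0)))
    hop = max(1, int(round(config.hop_ms * sr / 1000.0)))
    starts = np.arange(0, len(samples), hop)
    rms = np.empty(len(starts))
    sq = samples**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    ends = np.minimum(starts + frame, len(samples))
    rms = np.sqrt((csum[ends] - csum[starts]) / np.maximum(ends - starts, 1))
    with np.errstate(divide="ignore"):
        dbfs = 20.0 * np.log10(rms)
    return dbfs, starts / sr


def detect_silences(
    audio: AudioSignal,
    config: SegmenterConfig = SegmenterConfig(),
    min_silence_ms: float | None = None,
) -> list[TimeSpan]:
    """Maximal silent spans of at least ``min_silence_ms``.

    A span is silent when every analysis frame inside it has RMS below
    ``silence_threshold_dbfs``; spans are non-overlapping and time-ordered,
    with edges snapped to the hop grid.
    """
    if min_silence_ms is None:
        min_silence_ms = config.initial_min_silence_ms
    if min_silence_ms < config.silence_floor_ms:
        raise ValueError("min_silence_ms below silence_floor_ms")
    dbfs, starts = _frame_rms_dbfs(audio, config)
    threshold = config.silence_threshold_dbfs
    if config.adaptive_threshold:
        finite = dbfs[np.isfinite(dbfs)]
        if finite.size:
            threshold = float(np.percentile(finite, 10))
    silent = dbfs < threshold
    hop_s = config.hop_ms / 1000.0
    frame_s = config.frame_ms / 1000.0
    duration = audio.duration_s

    spans: list[TimeSpan] = []
    n = len(silent)
    i = 0
    while i < n:
        if not silent[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and silent[j + 1]:
            j += 1
        start = starts[i]
        end = min(starts[j] + frame_s, duration)
        # snap the end down to the hop grid unless it is the audio end
        if end < duration:
            end = round(end / hop_s) * hop_s
        if (end - start) * 1000.0 >= min_silence_ms:
            spans.append(TimeSpan(start, end))
        i = j + 1
    return spans


def _voiced_regions(total: TimeSpan, silences: list[TimeSpan]) -> list[TimeSpan]:
    regions = []
    cursor = total.start_s
    for s in silences:
        if s.start_s > cursor:
            regions.append(TimeSpan(cursor, s.start_s))
        cursor = max(cursor, s.end_s)
    if cursor < total.end_s:
        regions.append(TimeSpan(cursor, total.end_s))
    return regions


def _force_split(audio: AudioSignal, region: TimeSpan, config: SegmenterConfig) -> list[TimeSpan]:
    """Split an unbreakable over-long region at its lowest-energy interior frame.

    The split point is restricted to the central half of the region so both
    halves shrink geometrically; recursion therefore terminates with all
    pieces at most ``max_segment_s``. Never splits mid-frame: cut points lie
    on the hop grid.
    """
    if region.duration_s <= config.max_segment_s:
        return [region]
    clip = audio.slice(region)
    dbfs, starts = _frame_rms_dbfs(clip, config)
    lo, hi = 0.25 * clip.duration_s, 0.75 * clip.duration_s
    interior = (starts >= lo) & (starts <= hi)
    if not interior.any():  # degenerate: tiny region, cut at midpoint frame
        idx = len(starts) // 2
    else:
        candidates = np.where(interior)[0]
        idx = candidates[np.argmin(dbfs[candidates])]
    cut = region.start_s + starts[idx]
    if cut <= region.start_s or cut >= region.end_s:
        cut = region.start_s + region.duration_s / 2.0
    left, right = TimeSpan(region.start_s, cut), TimeSpan(cut, region.end_s)
    return _force_split(audio, left, config) + _force_split(audio, right, config)


def _split_region(audio: AudioSignal, region: TimeSpan, config: SegmenterConfig, min_silence_ms: float) -> list[TimeSpan]:
    if region.duration_s <= config.max_segment_s:
        return [region]
    if min_silence_ms < config.silence_floor_ms:
        return _force_split(audio, region, config)
    silences = detect_silences(audio.slice(region), config, min_silence_ms)
    offset = [
        TimeSpan(region.start_s + s.start_s, region.start_s + s.end_s) for s in silences
    ]
    sub = _voiced_regions(region, offset)
    if sub == [region]:  # no usable silence at this level: halve and retry
        return _split_region(audio, region, config, min_silence_ms / 2.0)
    out: list[TimeSpan] = []
    for r in sub:
        out.extend(_split_region(audio, r, config, min_silence_ms / 2.0))
    return out


def _merge_short(spans: list[TimeSpan], config: SegmenterConfig) -> list[TimeSpan]:
    """Merge segments shorter than ``min_segment_s`` into the shorter neighbor.

    The merge is skipped when it would exceed ``max_segment_s``; a short
    segment with no viable neighbor is kept. The merged span covers the
    silence between the two segments.
    """
    spans = list(spans)
    changed = True
    while changed:
        changed = False
        for i, span in enumerate(spans):
            if span.duration_s >= config.min_segment_s:
                continue
            neighbors = []
            if i > 0:
                neighbors.append(i - 1)
            if i + 1 < len(spans):
                neighbors.append(i + 1)
            neighbors.sort(key=lambda k: spans[k].duration_s)
            for k in neighbors:
                lo = min(spans[k].start_s, span.start_s)
                hi = max(spans[k].end_s, span.end_s)
                if hi - lo <= config.max_segment_s:
                    merged = TimeSpan(lo, hi)
                    a, b = sorted((i, k))
                    spans[a:b + 1] = [merged]
                    changed = True
                    break
            if changed:
                break
    return spans


def split_recursive(audio: AudioSignal, config: SegmenterConfig = SegmenterConfig()) -> list[TimeSpan]:
    """Split a recording into voiced segments of at most ``max_segment_s``.

    First pass cuts at silences of at least ``initial_min_silence_ms``; any
    over-long segment is re-split with the minimum silence halved, down to
    ``silence_floor_ms``, then force-split. Returned spans are disjoint,
    time-ordered, cover every voiced frame, and exclude detected silences.
    """
    duration = audio.duration_s
    if duration <= 0:
        raise InvalidAudioError("empty audio")
    total = TimeSpan(0.0, duration)
    silences = detect_silences(audio, config, config.initial_min_silence_ms)
    regions = _voiced_regions(total, silences)
    # drop regions that are entirely silent at the frame level (e.g. a short
    # sub-threshold-duration silent tail)
    spans: list[TimeSpan] = []
    for region in regions:
        spans.extend(_split_region(audio, region, config, config.initial_min_silence_ms / 2.0))
    spans = _merge_short(spans, config)
    return sorted(spans)
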