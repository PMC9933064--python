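"""Synthetic interview fixtures: audio with planted utterances and silences.

Real interview recordings and their transcripts are private, so every
pipeline stage is exercised on generated data with known ground truth:
multi-utterance audio whose utterance boundaries, per-utterance texts and
silence durations are chosen (and recorded) exactly, plus a text corrupter
that injects word-level insertions, deletions and substitutions at known
rates. The pipeline never interprets audio content — only frame energy — so
"speech" is simulated as tone bursts or band-limited noise at a controlled
level above a noise floor; acoustic realism is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .audioseg import AudioSignal, TimeSpan
from .textnorm import NormalizedText

__all__ = [
    "SynthSpec",
    "SynthInterview",
    "DEFAULT_VOCABULARY",
    "generate_interview",
    "corrupt_text",
]

# 200 stable Dutch-like words: single-token and unchanged under normalization.
DEFAULT_VOCABULARY: tuple[str, ...] = tuple(
    "de het een en van in is dat op te zijn met voor niet aan er om ook als maar "
    "dan bij nog naar dit zo over geen kan wel uit tot mij hij wij zij je ik "
    "we ze al naast onder tussen achter boven binnen buiten sinds tegen zonder "
    "door langs rond vanaf richting huis kamer deur raam tafel stoel bed keuken "
    "tuin gang trap muur vloer straat dorp stad land water lucht zon maan "
    "dag nacht week maand jaar uur tijd keer leven zorg hulp werk rust eten "
    "drinken slapen lopen zitten staan liggen praten luisteren kijken denken "
    "voelen weten vinden maken doen gaan komen blijven worden hebben krijgen "
    "geven nemen houden brengen halen zoeken vragen zeggen vertellen noemen "
    "familie moeder vader zoon dochter broer kind mens vrouw man buurman "
    "vriend verzorger dokter zuster meneer mevrouw naam woord verhaal vraag "
    "antwoord gesprek stem geluid stilte muziek boek krant brief foto ding "
    "spul kast klok bloem plant boom gras vogel hond kat vis koffie thee brood "
    "kaas soep appel mooi lelijk groot klein oud jong nieuw goed slecht "
    "warm koud licht donker stil druk blij moe ziek arm rijk "
    "vrolijk rustig aardig lief fijn zwaar makkelijk moeilijk lang "
.split())
assert len(DEFAULT_VOCABULARY) == 200


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic interview.

    Durations are sampled uniformly from the given (low, high) ranges.
    Speech is planted at ``speech_level_dbfs`` RMS over a Gaussian noise
    floor at ``noise_floor_dbfs``; defaults leave ~35 dB between speech and
    floor, comfortably straddling the segmenter's -40 dBFS threshold.
    """

    n_utterances: int = 10
    utterance_duration_s: tuple[float, float] = (2.0, 8.0)
    silence_duration_ms: tuple[float, float] = (300.0, 900.0)
    sample_rate: int = 16_000
    speech_model: str = "band_noise"
    speech_level_dbfs: float = -20.0
    noise_floor_dbfs: float = -55.0
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    words_per_utterance: tuple[int, int] = (4, 14)
    error_injection: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (ins, del, sub)
    group_label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speech_level_dbfs <= self.noise_floor_dbfs:
            raise ValueError("speech_level_dbfs must exceed noise_floor_dbfs")
        if any(not 0.0 <= r <= 1.0 for r in self.error_injection):
            raise ValueError("error-injection rates must be in [0, 1]")
        if self.speech_model not in ("tone_burst", "band_noise"):
            raise ValueError(f"unknown speech_model {self.speech_model!r}")
        if self.n_utterances < 0:
            raise ValueError("n_utterances must be >= 0")


@dataclass(frozen=True)
class SynthInterview:
    """Generated audio plus exact ground truth.

    ``transcript`` is the concatenation of the per-utterance texts —
    mirroring a full-length manual transcript without timestamps.
    """

    audio: AudioSignal
    transcript: NormalizedText
    true_boundaries: tuple[TimeSpan, ...] = field(default_factory=tuple)
    true_utterance_texts: tuple[NormalizedText, ...] = field(default_factory=tuple)
    group_label: str | None = None


def _dbfs_to_rms(dbfs: float) -> float:
    return 10.0 ** (dbfs / 20.0)


def _speech_samples(rng: np.random.Generator, n: int, sr: int, model: str, level_dbfs: float) -> np.ndarray:
    rms = _dbfs_to_rms(level_dbfs)
    if model == "tone_burst":
        freq = rng.uniform(200.0, 1000.0)
        t = np.arange(n) / sr
        x = np.sqrt(2.0) * rms * np.sin(2.0 * np.pi * freq * t)
    else:  # band_noise: white noise band-limited to the speech band
        x = rng.standard_normal(n)
        sos = butter(4, [300.0, 3400.0], btype="bandpass", fs=sr, output="sos")
        x = sosfilt(sos, x)
        x *= rms / max(np.sqrt(np.mean(x**2)), 1e-12)
    # short cosine fade at the edges avoids clicks at segment boundaries
    fade = min(int(0.01 * sr), n // 2)
    if fade > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(fade) / fade))
        x[:fade] *= ramp
        x[-fade:] *= ramp[::-1]
    return x


def generate_interview(spec: SynthSpec) -> SynthInterview:
    """Build one synthetic interview, deterministic given ``spec.seed``.

    The recording starts and ends with a silence drawn from the configured
    silence range; true utterance boundaries are recorded exactly as planted.
    A zero-utterance spec yields 1 s of noise floor and an empty transcript.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    floor_rms = _dbfs_to_rms(spec.noise_floor_dbfs)

    if spec.n_utterances == 0:
        samples = floor_rms * rng.standard_normal(sr)
        return SynthInterview(
            audio=AudioSignal(sr, np.clip(samples, -1.0, 1.0)),
            transcript=NormalizedText(()),
            group_label=spec.group_label,
        )

    chunks: list[np.ndarray] = []
    boundaries: list[TimeSpan] = []
    texts: list[NormalizedText] = []
    cursor = 0

    def add_silence() -> None:
        nonlocal cursor
        dur_ms = rng.uniform(*spec.silence_duration_ms)
        n = int(round(dur_ms * sr / 1000.0))
        chunks.append(floor_rms * rng.standard_normal(n))
        cursor += n

    add_silence()
    for _ in range(spec.n_utterances):
        dur = rng.uniform(*spec.utterance_duration_s)
        n = int(round(dur * sr))
        n_words = int(rng.integers(spec.words_per_utterance[0], spec.words_per_utterance[1] + 1))
        words = tuple(rng.choice(spec.vocabulary) for _ in range(n_words))
        speech = _speech_samples(rng, n, sr, spec.speech_model, spec.speech_level_dbfs)
        speech = speech + floor_rms * rng.standard_normal(n)
        chunks.append(speech)
        boundaries.append(TimeSpan(cursor / sr, (cursor + n) / sr))
        texts.append(NormalizedText(words))
        cursor += n
        add_silence()

    samples = np.clip(np.concatenate(chunks), -1.0, 1.0)
    transcript = NormalizedText(tuple(tok for t in texts for tok in t.tokens))
    return SynthInterview(
        audio=AudioSignal(sr, samples),
        transcript=transcript,
        true_boundaries=tuple(boundaries),
        true_utterance_texts=tuple(texts),
        group_label=spec.group_label,
    )


def corrupt_text(
    truth: NormalizedText,
    rates: tuple[float, float, float],
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    seed: int | np.random.Generator = 0,
) -> NormalizedText:
    """Corrupt a token sequence with per-word edit events at known rates.

    ``rates`` is (insertion, deletion, substitution). Per word: it is deleted
    with the deletion probability, else substituted by a *different*
    vocabulary word with the substitution probability; independently, an
    insertion event adds a random vocabulary word after the word's position.

    Planted events are kept identifiable under minimal-edit measurement: an
    insertion too close to a deletion would be re-explained by a Levenshtein
    alignment as a substitution chain (a strictly cheaper or tie-broken
    path). The shift costs one extra edit per *matched* word it crosses, and
    substituted positions cost nothing extra, so each insertion event is
    relocated to the nearest slot separated from every deletion by at least
    two matched words. Event counts are preserved; only placement moves.
    Deterministic given ``seed``.
    """
    ins_rate, del_rate, sub_rate = rates
    for r in (ins_rate, del_rate, sub_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    if del_rate + sub_rate > 1.0:
        raise ValueError("deletion + substitution rate cannot exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(truth.tokens)

    kept: list[str | None] = []  # None marks a deletion
    ins_events: list[int] = []  # slot j = insertion after word j
    for j, tok in enumerate(truth.tokens):
        u = rng.random()
        if u < del_rate:
            kept.append(None)
        elif u < del_rate + sub_rate:
            repl = tok
            while repl == tok:
                repl = str(rng.choice(vocabulary))
            kept.append(repl)
        else:
            kept.append(tok)
        if rng.random() < ins_rate:
            ins_events.append(j)

    deleted = [j for j, tok in enumerate(kept) if tok is None]
    matched = [tok is not None and tok == truth.tokens[j] for j, tok in enumerate(kept)]
    pref = [0]
    for m in matched:
        pref.append(pref[-1] + m)

    def _matched_between(i: int, j: int) -> int:
        lo, hi = (i + 1, j) if j >= i else (j + 1, i - 1)
        return pref[hi + 1] - pref[lo] if hi >= lo else 0

    safe = [all(_matched_between(i, j) >= 2 for i in deleted) for j in range(n)]
    inserts: dict[int, list[str]] = {}
    for j in ins_events:
        slot = next((k for k in range(j, n) if safe[k]), None)
        if slot is None:
            slot = next((k for k in range(j - 1, -1, -1) if safe[k]), None)
        word = str(rng.choice(vocabulary))
        if slot is not None:
            inserts.setdefault(slot, []).append(word)

    out: list[str] = []
    for j, tok in enumerate(kept):
        if tok is not None:
            out.append(tok)
        out.extend(inserts.get(j, ()))
    return NormalizedText(tuple(out))
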