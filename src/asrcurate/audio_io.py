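"""WAV reading and writing with a single internal format: 16 kHz mono float.

Input may be 8/16/32-bit PCM or float, mono or stereo (stereo is downmixed
by channel averaging); everything is rescaled to [-1, 1] and resampled to
the internal rate with a polyphase filter. Output is always 16-bit PCM mono.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .audioseg import INTERNAL_RATE, AudioSignal

__all__ = ["read_audio", "write_audio"]


def read_audio(path: str | Path, target_rate: int = INTERNAL_RATE) -> AudioSignal:
    """Read a WAV file as mono float samples in [-1, 1] at ``target_rate``."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    raw_dtype = data.dtype
    data = data.astype(np.float64)
    if data.ndim == 2:
        if data.shape[1] > 2:
            raise IOError(f"{path}: expected 1-2 channels, got {data.shape[1]}")
        data = data.mean(axis=1)
    if raw_dtype == np.int16:
        data /= 2**15
    elif raw_dtype == np.int32:  # 24-bit PCM also arrives as int32
        data /= 2**31
    elif raw_dtype == np.uint8:  # 8-bit WAV is offset binary
        data = (data - 128.0) / 128.0
    samples = np.clip(data, -1.0, 1.0)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        samples = resample_poly(samples, target_rate // g, rate // g)
        samples = np.clip(samples, -1.0, 1.0)
    return AudioSignal(sample_rate=target_rate, samples=samples)


def write_audio(path: str | Path, audio: AudioSignal) -> None:
    """Write 16-bit PCM mono WAV."""
    path = Path(path)
    pcm = np.clip(audio.samples, -1.0, 1.0)
    pcm = (pcm * (2**15 - 1)).astype(np.int16)
    wavfile.write(path, audio.sample_rate, pcm)
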