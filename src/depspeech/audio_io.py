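"""Mono WAV reading, writing and resampling.

This is the only module that touches sound files.  Downstream processing
assumes 16 kHz input; :func:`read_wav` deliberately does NOT resample, the
pipeline calls :func:`resample` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioSignal", "read_wav", "write_wav", "resample"]

TARGET_RATE = 16_000  # Hz; every downstream stage assumes this rate


@dataclass
class AudioSignal:
    """A mono sampled waveform with amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate


_PCM_SCALE = {
    np.dtype(np.int16): 2 ** 15,
    np.dtype(np.int32): 2 ** 31,
}


def read_wav(path) -> AudioSignal:
    """Read a RIFF/WAV file as a mono :class:`AudioSignal`.

    Multi-channel audio is averaged to mono; integer PCM is scaled to
    [-1, 1] by the full-scale value of its dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples, int(rate))


def write_wav(path, sig: AudioSignal) -> None:
    """Write as 16-bit PCM.

    Scaling by 2**15 (the same full-scale used on read) keeps the
    write-read round trip within one quantization step, |error| <= 2**-15.
    """
    pcm = np.clip(np.round(sig.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), sig.sample_rate, pcm)


def resample(sig: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resampling to ``target_rate``.

    The output has exactly ``round(len(sig) * target / source)`` samples
    (the polyphase result is trimmed or zero-padded by at most one sample).
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == sig.sample_rate:
        return AudioSignal(sig.samples.copy(), sig.sample_rate)
    frac = Fraction(int(target_rate), int(sig.sample_rate))
    out = resample_poly(sig.samples, frac.numerator, frac.denominator)
    n_target = int(round(len(sig) * target_rate / sig.sample_rate))
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return AudioSignal(out, target_rate)
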