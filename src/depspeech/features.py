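"""Frame-level speech features: 40-band log-mel filterbanks, 39-dimensional
MFCCs, delta dynamics, the stacked static/delta/delta-delta "3D" feature,
and the fixed-length padding policy used for batching.

Two feature families feed the two architectures:

* ``mfcc39`` -- 13 static mel-cepstral coefficients plus their first- and
  second-order dynamics (39 columns per frame), the baseline network input.
* ``fbank`` + ``stack_3d`` -- 40 log-mel filterbank energies per frame with
  delta and delta-delta stacked on a third axis, giving a frames x 40 x 3
  array, the 3D-network input.

The delta operator supports two conventions.  ``difference`` is the standard
regression formula

    m'_i = sum_n n (m_{i+n} - m_{i-n}) / (2 sum_n n^2)

which is zero on constant input.  ``printed_sum`` replaces the inner minus
with a plus, turning the operator into a smoother whose value on a constant
c is c * (sum n)/(sum n^2); it is kept for fidelity experiments against
sources that typeset the formula that way.  Boundary frames are replicated
in both conventions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from .audio_io import AudioSignal

__all__ = [
    "FeatureConfig",
    "Feature3D",
    "PaddedBatch",
    "fbank",
    "mfcc39",
    "delta",
    "stack_3d",
    "compute_padding_length",
    "pad_or_split",
]

LOG_FLOOR = 1e-10  # filterbank energies are clipped here before the log


@dataclass
class FeatureConfig:
    frame_length_s: float = 0.025
    frame_step_s: float = 0.010
    n_mel: int = 40
    n_mfcc_static: int = 13
    delta_window_N: int = 2
    delta_sign: str = "difference"  # or "printed_sum"
    preemphasis: float = 0.97

    def __post_init__(self):
        if self.delta_window_N < 1:
            raise ValueError("delta_window_N must be >= 1")
        if self.delta_sign not in ("difference", "printed_sum"):
            raise ValueError(f"unknown delta_sign {self.delta_sign!r}")
        if self.frame_length_s <= 0 or self.frame_step_s <= 0:
            raise ValueError("frame lengths must be positive")


@dataclass
class Feature3D:
    """frames x n_mel x 3 array; channels are (static, delta, delta-delta)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError(f"expected frames x bands x 3, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class PaddedBatch:
    """Fixed-length feature chunks stacked for the network, plus a mask of
    real (non-padded) frames."""

    tensors: np.ndarray  # batch x L x ... feature dims
    mask: np.ndarray     # batch x L booleans

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[:2] != self.mask.shape:
            raise ValueError("tensors and mask disagree on batch/frame axes")

    def __len__(self) -> int:
        return self.tensors.shape[0]

    @classmethod
    def from_items(cls, items, masks) -> "PaddedBatch":
        return cls(np.stack(items, axis=0), np.stack(masks, axis=0))


# ---------------------------------------------------------------------------
# spectral front end


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mel: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filters (n_mel x n_fft//2+1), HTK mel scale, 0..Nyquist."""
    nyquist = sample_rate / 2.0
    mel_points = np.linspace(_hz_to_mel(0.0), _hz_to_mel(nyquist), n_mel + 2)
    hz_points = _mel_to_hz(mel_points)
    bins = np.floor((n_fft + 1) * hz_points / sample_rate).astype(int)
    fb = np.zeros((n_mel, n_fft // 2 + 1))
    for m in range(1, n_mel + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        for k in range(left, center):
            if center > left:
                fb[m - 1, k] = (k - left) / (center - left)
        for k in range(center, right):
            if right > center:
                fb[m - 1, k] = (right - k) / (right - center)
    return fb


def _frames(sig: AudioSignal, cfg: FeatureConfig):
    frame_len = int(round(cfg.frame_length_s * sig.sample_rate))
    step = int(round(cfg.frame_step_s * sig.sample_rate))
    if len(sig) < frame_len:
        raise ValueError(
            f"signal of {len(sig)} samples is shorter than one "
            f"{frame_len}-sample frame"
        )
    x = sig.samples
    if cfg.preemphasis > 0:
        x = np.concatenate([x[:1], x[1:] - cfg.preemphasis * x[:-1]])
    n_frames = (len(x) - frame_len) // step + 1
    idx = np.arange(frame_len)[None, :] + step * np.arange(n_frames)[:, None]
    return x[idx], frame_len


def fbank(sig: AudioSignal, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Per-frame log-mel filterbank energies (frames x n_mel).

    Frame count is floor((len - frame_len)/step) + 1 -- no end padding.
    """
    cfg = cfg or FeatureConfig()
    frames, frame_len = _frames(sig, cfg)
    n_fft = 1 << (frame_len - 1).bit_length()
    window = np.hamming(frame_len)
    spectrum = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mel, n_fft, sig.sample_rate)
    energies = spectrum @ fb.T
    return np.log(np.maximum(energies, LOG_FLOOR))


def mfcc39(sig: AudioSignal, cfg: FeatureConfig | None = None) -> np.ndarray:
    """13 static MFCCs with delta and delta-delta appended (frames x 39)."""
    cfg = cfg or FeatureConfig()
    logmel = fbank(sig, cfg)
    static = dct(logmel, type=2, norm="ortho", axis=1)[:, :cfg.n_mfcc_static]
    d1 = delta(static, cfg.delta_window_N, cfg.delta_sign)
    d2 = delta(d1, cfg.delta_window_N, cfg.delta_sign)
    return np.concatenate([static, d1, d2], axis=1)


def delta(m: np.ndarray, N: int = 2, sign: str = "difference") -> np.ndarray:
    """Delta dynamics over a +/-N frame window with edge replication."""
    if N < 1:
        raise ValueError(f"delta window N must be >= 1, got {N}")
    m = np.asarray(m, dtype=np.float64)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[:, None]
    T = m.shape[0]
    denom = 2.0 * sum(n * n for n in range(1, N + 1))
    out = np.zeros_like(m)
    idx = np.arange(T)
    for n in range(1, N + 1):
        plus = m[np.clip(idx + n, 0, T - 1)]
        minus = m[np.clip(idx - n, 0, T - 1)]
        if sign == "difference":
            out += n * (plus - minus)
        elif sign == "printed_sum":
            out += n * (plus + minus)
        else:
            raise ValueError(f"unknown delta sign convention {sign!r}")
    return (out / denom)[:, 0] if squeeze else out / denom


def stack_3d(static: np.ndarray, cfg: FeatureConfig | None = None) -> Feature3D:
    """Stack static, delta and delta-delta channels into frames x 40 x 3."""
    cfg = cfg or FeatureConfig()
    static = np.asarray(static, dtype=np.float64)
    if static.ndim != 2 or static.shape[1] != cfg.n_mel:
        raise ValueError(
            f"expected frames x {cfg.n_mel} static features, got {static.shape}"
        )
    d1 = delta(static, cfg.delta_window_N, cfg.delta_sign)
    d2 = delta(d1, cfg.delta_window_N, cfg.delta_sign)
    return Feature3D(np.stack([static, d1, d2], axis=2))


# ---------------------------------------------------------------------------
# fixed-length batching policy


def compute_padding_length(lengths) -> int:
    """Modal frame count across utterances; ties break to the smaller value."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("need at least one utterance length")
    if any(int(x) != x or x < 1 for x in lengths):
        raise ValueError("lengths must be positive integers")
    counts = Counter(int(x) for x in lengths)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def pad_or_split(feat, L: int, discard_fraction: float = 0.1):
    """Split long items into chunks of L frames; zero-pad short remainders.

    Chunks whose real-frame count is strictly below ``discard_fraction * L``
    are discarded.  Returns ``(chunks, masks)`` where each chunk has exactly
    L frames and each mask marks the real (non-padded) frames.
    """
    if L < 1:
        raise ValueError(f"padding length must be >= 1, got {L}")
    values = feat.values if isinstance(feat, Feature3D) else np.asarray(feat)
    T = values.shape[0]
    trailing = values.shape[1:]
    chunks, masks = [], []
    for start in range(0, max(T, 1), L):
        piece = values[start:start + L]
        real = piece.shape[0]
        if real == 0 or real < discard_fraction * L:
            continue
        if real < L:
            pad_width = [(0, L - real)] + [(0, 0)] * len(trailing)
            piece = np.pad(piece, pad_width)
        mask = np.zeros(L, dtype=bool)
        mask[:real] = True
        chunks.append(piece)
        masks.append(mask)
    return chunks, masks
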