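"""Energy-based voice activity detection and fixed-length segmentation.

Silence removal is a self-contained short-time-energy gate: a frame is kept
when its energy reaches ``energy_threshold_ratio`` times the median frame
energy of the utterance.  The threshold is data-adaptive, so the gate is
scale-invariant; it is idempotent whenever speech and silence energies are
well separated (the bimodal case it is designed for).  Segmentation cuts the
gated signal into consecutive non-overlapping windows of fixed duration
(default 1.5 s) and discards the trailing remainder, so every training
sample has identical length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal

__all__ = ["VadConfig", "SegmentSet", "remove_silence", "cut_segments"]

_ENERGY_FLOOR = 1e-12  # digital silence never passes the gate


@dataclass
class VadConfig:
    window_s: float = 0.020
    step_s: float = 0.020
    energy_threshold_ratio: float = 0.1
    min_speech_s: float = 0.0

    def __post_init__(self):
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if not 0.0 < self.energy_threshold_ratio < 1.0:
            raise ValueError("energy_threshold_ratio must be in (0, 1)")
        if self.min_speech_s < 0:
            raise ValueError("min_speech_s must be non-negative")


@dataclass
class SegmentSet:
    """Equal-length audio segments cut from one participant's speech."""

    segments: list
    source_id: str | None = None
    n_dropped_samples: int = 0

    def __post_init__(self):
        if self.segments:
            n = len(self.segments[0])
            rate = self.segments[0].sample_rate
            for seg in self.segments:
                if len(seg) != n or seg.sample_rate != rate:
                    raise ValueError("segments must share one length and rate")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def segment_length(self) -> int:
        return len(self.segments[0]) if self.segments else 0


def _frame_energies(x: np.ndarray, win: int, step: int):
    """Per-frame mean-square energy plus the sample span each frame owns.

    Frames start every ``step`` samples; energy is measured over ``win``
    samples (the final, possibly partial, frame is measured over what
    remains).  A frame owns the samples [start, start+step) so that
    concatenating kept frames never duplicates audio even when win > step.
    """
    starts = list(range(0, len(x), step))
    energies = np.empty(len(starts))
    for k, s in enumerate(starts):
        frame = x[s:s + win]
        energies[k] = float(np.mean(frame ** 2)) if frame.size else 0.0
    return starts, energies


def remove_silence(sig: AudioSignal, cfg: VadConfig | None = None) -> AudioSignal:
    """Drop frames whose short-time energy falls below the adaptive threshold.

    Returns the concatenation of the surviving frames (possibly empty --
    an all-silent input yields a zero-length signal, which the caller must
    handle).
    """
    if len(sig) == 0:
        raise ValueError("cannot run silence removal on an empty signal")
    cfg = cfg or VadConfig()
    win = max(1, int(round(cfg.window_s * sig.sample_rate)))
    step = max(1, int(round(cfg.step_s * sig.sample_rate)))
    starts, energies = _frame_energies(sig.samples, win, step)
    threshold = max(cfg.energy_threshold_ratio * float(np.median(energies)),
                    _ENERGY_FLOOR)
    keep = energies >= threshold

    if cfg.min_speech_s > 0:
        min_frames = int(np.ceil(cfg.min_speech_s * sig.sample_rate / step))
        keep = _drop_short_runs(keep, min_frames)

    pieces = [sig.samples[s:s + step] for s, k in zip(starts, keep) if k]
    out = np.concatenate(pieces) if pieces else np.empty(0)
    return AudioSignal(out, sig.sample_rate)


def _drop_short_runs(keep: np.ndarray, min_frames: int) -> np.ndarray:
    out = keep.copy()
    run_start = None
    for i, k in enumerate(list(keep) + [False]):
        if k and run_start is None:
            run_start = i
        elif not k and run_start is not None:
            if i - run_start < min_frames:
                out[run_start:i] = False
            run_start = None
    return out


def cut_segments(sig: AudioSignal, segment_s: float = 1.5,
                 source_id: str | None = None) -> SegmentSet:
    """Cut into consecutive windows of ``segment_s`` seconds.

    The trailing remainder shorter than one segment is discarded; an input
    shorter than one segment yields an empty set.
    """
    if segment_s <= 0:
        raise ValueError(f"segment_s must be positive, got {segment_s}")
    seg_len = int(round(segment_s * sig.sample_rate))
    n_seg = len(sig) // seg_len
    segments = [
        AudioSignal(sig.samples[i * seg_len:(i + 1) * seg_len], sig.sample_rate)
        for i in range(n_seg)
    ]
    return SegmentSet(segments, source_id=source_id,
                      n_dropped_samples=len(sig) - n_seg * seg_len)
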