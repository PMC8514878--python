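"""Seeded generator of two-class synthetic speech-like audio.

Clinical observations motivate the contrast between the classes: depressed
speech tends toward slower speaking rate, lower and flatter pitch, weaker
and less variable intensity, and a larger share of pauses.  Each utterance
is a parametric harmonic-plus-noise rendering of those cues: a sequence of
voiced "syllables" (a fundamental drawn per syllable from
Normal(f0_mean, f0_sd) plus two harmonics at -6 and -12 dB under a
raised-cosine envelope, amplitude jittered by ``amplitude_sd``) separated
by silent pauses whose total share matches ``pause_fraction``, over a bed
of white noise at ``noise_snr_db``.

The audio is not intelligible speech and is not meant to be: the pipeline
only requires class-separable spectro-temporal structure.  A fixed seed
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .audio_io import AudioSignal, write_wav
from .phq_labels import ITEM_FIELDS, PHQ8Record, save_manifest

__all__ = [
    "ClassAcousticProfile",
    "CorpusSpec",
    "default_profiles",
    "generate_utterance",
    "generate_corpus",
]


@dataclass(frozen=True)
class ClassAcousticProfile:
    f0_mean: float          # Hz, per-syllable fundamental mean
    f0_sd: float            # Hz, between-syllable pitch variability
    syllable_rate: float    # voiced events per second
    pause_fraction: float   # share of the utterance that is silent
    amplitude: float        # peak fraction of full scale
    amplitude_sd: float     # relative amplitude jitter between syllables
    noise_snr_db: float = 30.0

    def __post_init__(self):
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        if self.f0_sd < 0 or self.amplitude_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.pause_fraction < 1.0:
            raise ValueError("pause_fraction must be in [0, 1)")
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must be in (0, 1]")
        if self.syllable_rate <= 0:
            raise ValueError("syllable_rate must be positive")


def default_profiles() -> dict:
    """Contrasting control (0) and depressed (1) acoustic profiles."""
    return {
        0: ClassAcousticProfile(f0_mean=140.0, f0_sd=20.0, syllable_rate=3.5,
                                pause_fraction=0.15, amplitude=0.6,
                                amplitude_sd=0.15),
        1: ClassAcousticProfile(f0_mean=110.0, f0_sd=8.0, syllable_rate=2.0,
                                pause_fraction=0.35, amplitude=0.3,
                                amplitude_sd=0.05),
    }


@dataclass
class CorpusSpec:
    n_per_class: int = 20
    duration_s: float = 3.0
    sample_rate: int = 16_000
    seed: int = 0
    profiles: dict = field(default_factory=default_profiles)

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


_HARMONIC_GAINS = (1.0, 0.5, 0.25)  # fundamental, -6 dB, -12 dB
_RAMP_S = 0.010  # raised-cosine attack/release per syllable


def _syllable_envelope(n: int, rate: int) -> np.ndarray:
    """Flat envelope with short raised-cosine ramps.

    The ramps (10 ms) are brief relative to a 20 ms VAD frame, so a
    zero-pause utterance keeps every frame above the energy gate
    (a full-length cosine envelope would push syllable edges under it).
    """
    ramp = min(int(round(_RAMP_S * rate)), n // 2)
    env = np.ones(n)
    if ramp > 0:
        ramp_curve = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = ramp_curve
        env[-ramp:] = ramp_curve[::-1]
    return env


def generate_utterance(profile: ClassAcousticProfile, duration_s: float,
                       rate: int, seed: int) -> AudioSignal:
    """Render one syllable/pause utterance for the given acoustic profile."""
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * rate))
    n_syll = max(1, int(round(profile.syllable_rate * duration_s)))
    voiced_total = duration_s * (1.0 - profile.pause_fraction)
    syll_len = int(round(voiced_total / n_syll * rate))
    pause_total = max(0, n_total - n_syll * syll_len)
    # distribute the pause budget over n_syll + 1 gaps
    if pause_total > 0:
        shares = rng.dirichlet(np.ones(n_syll + 1))
        gap_lens = np.floor(shares * pause_total).astype(int)
        gap_lens[-1] += pause_total - gap_lens.sum()
    else:
        gap_lens = np.zeros(n_syll + 1, dtype=int)

    out = np.zeros(n_total)
    cursor = 0
    for s in range(n_syll):
        cursor += gap_lens[s]
        f0 = max(30.0, rng.normal(profile.f0_mean, profile.f0_sd))
        amp = profile.amplitude * max(0.05, 1.0 + rng.normal(0.0, profile.amplitude_sd))
        t = np.arange(syll_len) / rate
        wave = np.zeros(syll_len)
        for h, gain in enumerate(_HARMONIC_GAINS, start=1):
            wave += gain * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
        peak = np.abs(wave).max()
        if peak > 0:
            wave /= peak
        seg = amp * wave * _syllable_envelope(syll_len, rate)
        end = min(cursor + syll_len, n_total)  # rounding can overrun by a few samples
        out[cursor:end] = seg[:end - cursor]
        cursor += syll_len

    voiced_rms = np.sqrt(np.mean(out[np.abs(out) > 0] ** 2)) if np.any(out) else 1.0
    noise_rms = voiced_rms / (10.0 ** (profile.noise_snr_db / 20.0))
    out = out + rng.normal(0.0, noise_rms, size=n_total)
    peak = np.abs(out).max()
    if peak > 1.0:
        out *= 0.99 / peak
    return AudioSignal(out, rate)


def _synthetic_items(rng: np.random.Generator, label: int) -> tuple:
    """Random PHQ-8 item vector whose total is consistent with the label."""
    target = int(rng.integers(10, 25)) if label == 1 else int(rng.integers(0, 10))
    items = np.zeros(len(ITEM_FIELDS), dtype=int)
    while items.sum() < target:
        open_slots = np.flatnonzero(items < 3)
        items[rng.choice(open_slots)] += 1
    return tuple(int(v) for v in items)


def generate_corpus(spec: CorpusSpec, out_dir) -> tuple:
    """Write a labeled WAV directory plus manifest CSV.

    Returns ``(wav_paths, records, manifest_path)``.  The directory is a
    drop-in input for the full pipeline: one 16-bit PCM WAV per synthetic
    participant, named ``<participant_id>.wav``, and a ``manifest.csv`` in
    the schema of :func:`depspeech.phq_labels.load_manifest`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records, wav_paths = [], []
    for label in sorted(spec.profiles):
        profile = spec.profiles[label]
        for i in range(spec.n_per_class):
            pid = f"P{label}{i:03d}"
            utt_seed = int(rng.integers(0, 2 ** 31))
            sig = generate_utterance(profile, spec.duration_s, spec.sample_rate,
                                     utt_seed)
            wav_path = out_dir / f"{pid}.wav"
            write_wav(wav_path, sig)
            wav_paths.append(wav_path)
            records.append(
                PHQ8Record(
                    participant_id=pid,
                    gender=int(rng.integers(0, 2)),
                    items=_synthetic_items(rng, label),
                )
            )
    manifest_path = out_dir / "manifest.csv"
    save_manifest(records, manifest_path)
    return wav_paths, records, manifest_path
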