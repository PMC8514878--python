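"""High-level modelling interface.

`DepressionDetector` wraps the full pipeline behind a statsmodels-style
model object: build it from extracted features (or straight from a corpus
directory with :meth:`DepressionDetector.from_corpus`), call
:meth:`~DepressionDetector.fit`, and receive a :class:`DetectionResults`
carrying the trained network, the loss history, held-out predictions and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .audio_io import TARGET_RATE, read_wav, resample
from .features import (FeatureConfig, PaddedBatch, compute_padding_length,
                       fbank, mfcc39, pad_or_split, stack_3d)
from .metrics import MetricsReport, confusion, evaluate, format_table, participant_majority
from .network import ModelConfig, build_1dcbbg, build_3dcbhga
from .phq_labels import load_manifest
from .preprocess import VadConfig, cut_segments, remove_silence
from .training import TrainConfig, TrainingHistory, predict, train

__all__ = [
    "extract_corpus_features",
    "split_by_participant",
    "DepressionDetector",
    "DetectionResults",
]


def extract_corpus_features(audio_dir, manifest_path=None,
                            feature_kind: str = "fbank3d",
                            keep_silence: bool = False,
                            vad: VadConfig | None = None,
                            segment_s: float = 1.5,
                            feature_config: FeatureConfig | None = None):
    """Audio directory + manifest -> per-segment features and labels.

    Each participant's WAV is resampled to 16 kHz, optionally passed
    through silence removal, cut into fixed 1.5 s segments, and converted
    to either the frames x 40 x 3 filterbank stack (``fbank3d``) or
    frames x 39 MFCCs (``mfcc39``).  Returns ``(PaddedBatch, labels,
    participant_ids, padding_length)`` with one row per retained chunk.
    """
    if feature_kind not in ("fbank3d", "mfcc39"):
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    audio_dir = Path(audio_dir)
    manifest_path = Path(manifest_path or audio_dir / "manifest.csv")
    records = load_manifest(manifest_path)
    if not records:
        raise ValueError(f"manifest {manifest_path} has no rows")
    fcfg = feature_config or FeatureConfig()
    vad = vad or VadConfig()

    per_segment, labels, pids = [], [], []
    for rec in records:
        wav_path = audio_dir / f"{rec.participant_id}.wav"
        if not wav_path.exists():
            import warnings
            warnings.warn(f"no audio for participant {rec.participant_id}; skipped",
                          stacklevel=2)
            continue
        sig = resample(read_wav(wav_path), TARGET_RATE)
        if not keep_silence:
            sig = remove_silence(sig, vad)
            if len(sig) == 0:
                continue
        for seg in cut_segments(sig, segment_s, source_id=rec.participant_id).segments:
            if feature_kind == "fbank3d":
                feat = stack_3d(fbank(seg, fcfg), fcfg).values
            else:
                feat = mfcc39(seg, fcfg)
            per_segment.append(feat)
            labels.append(rec.label)
            pids.append(rec.participant_id)
    if not per_segment:
        raise ValueError(f"no usable audio found under {audio_dir}")

    L = compute_padding_length([f.shape[0] for f in per_segment])
    chunks, masks, chunk_labels, chunk_pids = [], [], [], []
    for feat, lab, pid in zip(per_segment, labels, pids):
        cs, ms = pad_or_split(feat, L)
        chunks.extend(cs)
        masks.extend(ms)
        chunk_labels.extend([lab] * len(cs))
        chunk_pids.extend([pid] * len(cs))
    batch = PaddedBatch.from_items(chunks, masks)
    return batch, np.asarray(chunk_labels), chunk_pids, L


def split_by_participant(participant_ids, labels, test_fraction: float = 0.3,
                         seed: int = 0):
    """Stratified train/test split at the participant level.

    Returns boolean masks (train, test) over segments; every participant's
    segments land on one side only.
    """
    pids = np.asarray(participant_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_pids = set()
    for cls in np.unique(labels):
        cls_pids = sorted(set(pids[labels == cls]))
        n_test = max(1, int(round(test_fraction * len(cls_pids))))
        chosen = rng.choice(len(cls_pids), size=n_test, replace=False)
        test_pids.update(cls_pids[i] for i in chosen)
    test_mask = np.array([p in test_pids for p in pids])
    return ~test_mask, test_mask


class DepressionDetector:
    """A depression classifier specified by features, labels and configs.

    Parameters
    ----------
    X : ndarray
        Stacked feature batch -- (B, L, 40, 3) for the 3D attention model
        or (B, L, 39) for the 1D baseline; the architecture is inferred
        from the rank.
    y : ndarray
        Binary segment labels (1 = depressed).
    mask : ndarray, optional
        (B, L) booleans marking real frames.
    """

    def __init__(self, X, y, mask=None, participant_ids=None,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.X = np.asarray(X, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.int64)
        self.mask = None if mask is None else np.asarray(mask, dtype=bool)
        self.participant_ids = participant_ids
        if self.X.ndim == 4:
            arch = "2d"
        elif self.X.ndim == 3:
            arch = "1d"
        else:
            raise ValueError(f"cannot infer architecture from input rank {self.X.ndim}")
        self.model_config = model_config or ModelConfig(conv_dims=arch)
        if self.model_config.conv_dims != arch:
            raise ValueError(
                f"input rank implies conv_dims={arch!r} but config says "
                f"{self.model_config.conv_dims!r}"
            )
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_corpus(cls, audio_dir, manifest_path=None,
                    feature_kind: str = "fbank3d", keep_silence: bool = False,
                    model_config: ModelConfig | None = None,
                    train_config: TrainConfig | None = None,
                    **extract_kwargs) -> "DepressionDetector":
        batch, labels, pids, _ = extract_corpus_features(
            audio_dir, manifest_path, feature_kind=feature_kind,
            keep_silence=keep_silence, **extract_kwargs)
        return cls(batch.tensors, labels, mask=batch.mask, participant_ids=pids,
                   model_config=model_config, train_config=train_config)

    def build_network(self, seed: int = 0):
        if self.model_config.conv_dims == "2d":
            return build_3dcbhga(self.model_config, n_mel=self.X.shape[2],
                                 n_chan=self.X.shape[3], seed=seed)
        return build_1dcbbg(self.model_config, input_length=self.X.shape[1],
                            input_dim=self.X.shape[2], seed=seed)

    def fit(self, seed: int | None = None, X_val=None, y_val=None,
            mask_val=None) -> "DetectionResults":
        seed = self.train_config.seed if seed is None else seed
        cfg = TrainConfig(**{**asdict(self.train_config), "seed": seed})
        net = self.build_network(seed=seed)
        history = train(net, self.X, self.y, cfg, mask=self.mask,
                        X_val=X_val, y_val=y_val, mask_val=mask_val)
        return DetectionResults(self, net, history, cfg)


@dataclass
class DetectionResults:
    """A fitted detector: trained network, history and evaluation helpers."""

    model: DepressionDetector
    network: object
    history: TrainingHistory
    train_config: TrainConfig

    def predict(self, X, mask=None):
        return predict(self.network, X, mask=mask)

    def evaluate(self, X, y, mask=None, participant_ids=None,
                 truth_by_participant=None):
        """Segment-level report; participant-majority report when ids given."""
        _, labels = self.predict(X, mask=mask)
        out = {"segment": evaluate(labels, y)}
        if participant_ids is not None:
            order, voted = participant_majority(labels, participant_ids)
            truth = np.asarray([truth_by_participant[p] for p in order])
            out["participant"] = evaluate(voted, truth)
        return out

    def summary(self, eval_reports: dict | None = None) -> str:
        cfg = self.model.model_config
        lines = [
            "Depression detection model",
            "=" * 46,
            f"architecture:        {'3D-CBHGA' if cfg.conv_dims == '2d' else '1D-CBBG'}",
            f"kernel sizes:        {tuple(cfg.kernel_sizes)}",
            f"filters per branch:  {cfg.filters_per_branch}",
            f"GRU units:           {cfg.gru_units}",
            f"highway layers:      {cfg.n_highway}",
            f"training samples:    {self.model.X.shape[0]}",
            f"epochs run:          {len(self.history.loss)}",
            f"final mean loss:     {self.history.loss[-1]:.4f}",
            f"final train acc:     {self.history.train_acc[-1]:.3f}",
        ]
        if eval_reports:
            lines.append("")
            lines.append(format_table({k: v for k, v in eval_reports.items()}))
        return "\n".join(lines)
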