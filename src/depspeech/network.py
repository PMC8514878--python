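"""Model components and the two depression-detection architectures.

Components
----------
* **Multi-channel convolution** -- parallel same-padded convolution branches
  with kernel sizes 1, 2, 3, 4 (by default), concatenated on the channel
  axis; each branch sees a different local span of frames, analogous to
  n-gram windows over text.
* **Highway layer** -- a gated blend ``H(x) * T(x) + x * (1 - T(x))`` of a
  ReLU-affine transform H and the identity path, where the transform gate
  T is sigmoid-affine and the carry gate is tied to ``1 - T``.
* **Attention pooling** -- a learned scoring vector W gives one logit per
  recurrent time step; softmax weights (computed with max-subtraction)
  produce a convex combination of the step outputs.

Architectures
-------------
* ``build_1dcbbg`` -- the 1D baseline: multi-channel 1D convolution over
  39-dimensional MFCC frames, batch norm, max pooling, a single-channel
  convolution, a bidirectional GRU, flatten, softmax.
* ``build_3dcbhga`` -- the 3D model: multi-channel 2D convolution over the
  frames x 40 x 3 filterbank stack (same-size output), max pooling,
  highway layer(s), a second convolution, a bidirectional GRU pooled by
  attention, a dense softmax head.

Filter counts, pooling size, GRU width and dropout are configuration
fields with defaults, not architectural constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "HighwayParams",
    "AttentionParams",
    "multichannel_conv",
    "highway_forward",
    "attention_pool",
    "Highway",
    "AttentionPool",
    "CBBG1D",
    "CBHGA3D",
    "build_1dcbbg",
    "build_3dcbhga",
]


@dataclass
class ModelConfig:
    kernel_sizes: tuple = (1, 2, 3, 4)
    filters_per_branch: int = 32
    conv_dims: str = "2d"  # "1d" or "2d"
    pool_size: int = 2
    gru_units: int = 64
    n_highway: int = 1
    n_classes: int = 2
    dropout: float = 0.2
    second_conv_filters: int = 32
    second_conv_kernel: int = 3

    def __post_init__(self):
        if not self.kernel_sizes or any(k < 1 for k in self.kernel_sizes):
            raise ValueError("kernel_sizes must be non-empty, all >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.conv_dims not in ("1d", "2d"):
            raise ValueError(f"conv_dims must be '1d' or '2d', got {self.conv_dims}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class HighwayParams:
    """Hand-settable highway weights: H = relu(x W_H + b_H), T = sigmoid(x W_T + b_T)."""

    W_H: np.ndarray
    b_H: np.ndarray
    W_T: np.ndarray
    b_T: np.ndarray

    def __post_init__(self):
        self.W_H = np.atleast_2d(np.asarray(self.W_H, dtype=np.float64))
        self.W_T = np.atleast_2d(np.asarray(self.W_T, dtype=np.float64))
        self.b_H = np.atleast_1d(np.asarray(self.b_H, dtype=np.float64))
        self.b_T = np.atleast_1d(np.asarray(self.b_T, dtype=np.float64))
        for name, W in (("W_H", self.W_H), ("W_T", self.W_T)):
            if W.shape[0] != W.shape[1]:
                raise ValueError(f"{name} must be square (highway keeps width)")


@dataclass
class AttentionParams:
    """Scoring vector; one scalar logit per time step."""

    W: np.ndarray

    def __post_init__(self):
        self.W = np.atleast_1d(np.asarray(self.W, dtype=np.float64))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def highway_forward(x: np.ndarray, params: HighwayParams) -> np.ndarray:
    """Gated highway transform on plain arrays (reference path)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[-1] != params.W_H.shape[0]:
        raise ValueError(
            f"input width {x.shape[-1]} does not match highway width "
            f"{params.W_H.shape[0]}"
        )
    H = np.maximum(x @ params.W_H + params.b_H, 0.0)
    T = _sigmoid(x @ params.W_T + params.b_T)
    return H * T + x * (1.0 - T)


def attention_pool(P: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Softmax-weighted sum of per-step outputs (reference path).

    ``P`` is steps x width; weights are exp(W.p_t) normalised over steps,
    computed stably by subtracting the maximum logit.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("P must be a non-empty steps x width matrix")
    if P.shape[1] != params.W.shape[0]:
        raise ValueError("scoring vector width must match step output width")
    logits = P @ params.W
    alpha = np.exp(logits - logits.max())
    alpha /= alpha.sum()
    return alpha @ P


def multichannel_conv(x: np.ndarray, cfg: ModelConfig, params) -> np.ndarray:
    """Multi-branch same-padded convolution on plain arrays.

    ``params`` is one ``(W, b)`` pair per kernel size.  For 1D input
    (frames x D) each W is (k, D, filters); for 3D input (frames x D x C)
    each W is (k, k, C, filters).  Branch outputs concatenate on the
    channel axis; the frame axis is preserved by same padding.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(params) != len(cfg.kernel_sizes):
        raise ValueError("one (W, b) pair per kernel size required")
    outs = []
    for k, (W, b) in zip(cfg.kernel_sizes, params):
        W = np.asarray(W, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if cfg.conv_dims == "1d":
            if x.ndim != 2:
                raise ValueError("1d multichannel conv expects frames x D input")
            xt = Tensor(x[None, :, :])
            Wt = Tensor(W[:, None, :, :])
            y = nn.conv_same(xt.reshape(1, x.shape[0], 1, x.shape[1]), Wt, Tensor(b))
            outs.append(y.data[0, :, 0, :])
        else:
            if x.ndim != 3:
                raise ValueError("2d multichannel conv expects frames x D x C input")
            y = nn.conv_same(Tensor(x[None]), Tensor(W), Tensor(b))
            outs.append(y.data[0])
    return np.concatenate(outs, axis=-1)


# ---------------------------------------------------------------------------
# trainable modules


class Highway(nn.Module):
    """Trainable highway layer applied along the last (channel) axis."""

    def __init__(self, width: int, rng: np.random.Generator, dtype=np.float32,
                 carry_bias: float = -1.0):
        self.H = nn.Dense(width, width, rng, dtype)
        self.T = nn.Dense(width, width, rng, dtype)
        # negative gate bias starts the layer near the identity carry path
        self.T.b.data = np.full(width, carry_bias, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        flat = x.reshape(-1, x.shape[-1])
        h = self.H(flat).relu()
        t = self.T(flat).sigmoid()
        out = h * t + flat * (1.0 - t)
        return out.reshape(*x.shape)


class AttentionPool(nn.Module):
    """Trainable attention pooling over (B, T, D) sequences with a mask.

    The per-sample weights of the most recent forward pass are kept in
    ``last_alpha`` for inspection.
    """

    def __init__(self, width: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Tensor(nn.glorot(rng, (width, 1), dtype), requires_grad=True)
        self.last_alpha = None

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape
        logits = (x.reshape(-1, D) @ self.W).reshape(B, T)
        if mask is not None:
            bias = np.where(np.asarray(mask, dtype=bool), 0.0, -1e9)
            logits = logits + Tensor(bias.astype(logits.data.dtype))
        shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        alpha = e * _bcast_reciprocal(e.sum(axis=1, keepdims=True))
        self.last_alpha = alpha.data.copy()
        weighted = x * alpha.reshape(B, T, 1)
        return weighted.sum(axis=1)


def _bcast_reciprocal(t: Tensor) -> Tensor:
    out_data = 1.0 / t.data

    def bwd(g):
        if t.requires_grad:
            t._accumulate(-g * out_data * out_data)

    return Tensor(out_data, parents=(t,), backward=bwd)


class CBBG1D(nn.Module):
    """Baseline: multi-channel 1D conv + BN + pooling + conv + Bi-GRU + softmax.

    Input: (B, L, 39) MFCC batches; output: (B, n_classes) logits
    (softmax applied by the caller / training loss).
    """

    def __init__(self, cfg: ModelConfig, input_length: int, input_dim: int = 39,
                 seed: int = 0, dtype=np.float32):
        if cfg.conv_dims != "1d":
            raise ValueError("CBBG1D requires conv_dims='1d'")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.input_length = input_length
        self.input_dim = input_dim
        F = cfg.filters_per_branch
        self.branches = [
            nn.Conv1dSame(k, input_dim, F, rng, dtype) for k in cfg.kernel_sizes
        ]
        width = F * len(cfg.kernel_sizes)
        self.bn = nn.BatchNorm(width, dtype=dtype)
        self.conv2 = nn.Conv1dSame(cfg.second_conv_kernel, width,
                                   cfg.second_conv_filters, rng, dtype)
        self.gru = nn.BiGRU(cfg.second_conv_filters, cfg.gru_units, rng, dtype)
        pooled_len = max(1, input_length // cfg.pool_size)
        self.dropout = nn.Dropout(cfg.dropout, np.random.default_rng(seed + 1))
        self.head = nn.Dense(pooled_len * 2 * cfg.gru_units, cfg.n_classes, rng, dtype)

    def __call__(self, x, mask=None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ValueError(
                f"expected (B, L, {self.input_dim}) input, got {x.shape}"
            )
        y = nn.concat([b(x) for b in self.branches], axis=-1)
        y = self.bn(y).relu()
        y = y.max_pool((self.cfg.pool_size,))
        y = self.conv2(y).relu()
        y = self.gru(y)
        y = y.reshape(y.shape[0], -1)
        y = self.dropout(y)
        return self.head(y)


class CBHGA3D(nn.Module):
    """3D model: multi-channel 2D conv + pooling + highway + conv +
    attention-pooled Bi-GRU + dense softmax head.

    Input: (B, L, 40, 3) filterbank stacks; output: (B, n_classes) logits.
    Max pooling sits at the end of the first convolution stage (mirroring
    the baseline) so the highway and recurrent layers operate on the
    pooled grid.
    """

    def __init__(self, cfg: ModelConfig, n_mel: int = 40, n_chan: int = 3,
                 seed: int = 0, dtype=np.float32):
        if cfg.conv_dims != "2d":
            raise ValueError("CBHGA3D requires conv_dims='2d'")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_mel = n_mel
        self.n_chan = n_chan
        F = cfg.filters_per_branch
        self.branches = [
            nn.Conv2dSame(k, k, n_chan, F, rng, dtype) for k in cfg.kernel_sizes
        ]
        width = F * len(cfg.kernel_sizes)
        self.highways = [Highway(width, rng, dtype) for _ in range(cfg.n_highway)]
        k2 = cfg.second_conv_kernel
        self.conv2 = nn.Conv2dSame(k2, k2, width, cfg.second_conv_filters, rng, dtype)
        pooled_mel = max(1, n_mel // cfg.pool_size)
        gru_in = pooled_mel * cfg.second_conv_filters
        self.gru = nn.BiGRU(gru_in, cfg.gru_units, rng, dtype)
        self.attention = AttentionPool(2 * cfg.gru_units, rng, dtype)
        self.dropout = nn.Dropout(cfg.dropout, np.random.default_rng(seed + 1))
        self.head = nn.Dense(2 * cfg.gru_units, cfg.n_classes, rng, dtype)

    def _pooled_mask(self, mask: np.ndarray | None, pooled_T: int):
        if mask is None:
            return None
        p = self.cfg.pool_size
        m = np.asarray(mask, dtype=bool)
        trimmed = m[:, :pooled_T * p].reshape(m.shape[0], pooled_T, p)
        return trimmed.any(axis=2)

    def __call__(self, x, mask=None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[2] != self.n_mel or x.shape[3] != self.n_chan:
            raise ValueError(
                f"expected (B, L, {self.n_mel}, {self.n_chan}) input, got {x.shape}"
            )
        p = self.cfg.pool_size
        # relu and disjoint-window max pooling commute with each other and
        # with the channel concat, so pool per branch first: the big
        # same-size conv activations stay short-lived
        y = nn.concat([b(x).max_pool((p, p)).relu() for b in self.branches],
                      axis=-1)
        for hw in self.highways:
            y = hw(y)
        y = self.conv2(y).relu()
        B, T, Fm, C = y.shape
        y = y.reshape(B, T, Fm * C)
        y = self.gru(y)
        y = self.attention(y, self._pooled_mask(mask, T))
        y = self.dropout(y)
        return self.head(y)


def build_1dcbbg(cfg: ModelConfig, input_length: int, input_dim: int = 39,
                 seed: int = 0) -> CBBG1D:
    """Build the 1D baseline for a fixed padded length."""
    return CBBG1D(cfg, input_length=input_length, input_dim=input_dim, seed=seed)


def build_3dcbhga(cfg: ModelConfig, n_mel: int = 40, n_chan: int = 3,
                  seed: int = 0) -> CBHGA3D:
    """Build the 3D attention model."""
    return CBHGA3D(cfg, n_mel=n_mel, n_chan=n_chan, seed=seed)
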