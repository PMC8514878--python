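"""Minimal reverse-mode automatic differentiation on numpy arrays.

The layers here are the building blocks for the depression-detection
architectures: dense/affine maps, same-padded 1D/2D convolution, batch
normalization, max pooling, GRU cells and dropout, together with an Adam
optimizer and a weighted softmax cross-entropy loss.  Gradients are exact
(verified against central finite differences in the test suite).

Conventions
-----------
* Tensors carry ``data`` (ndarray) and, after ``backward()``, ``grad``.
* Convolutions use the machine-learning correlation convention and
  "same" zero padding along the spatial axes, so the frame axis of the
  output always matches the input.
* All randomness (initialisation, shuffling, dropout) flows through
  explicit ``numpy.random.Generator`` objects for bit-reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Dense",
    "Conv1dSame",
    "Conv2dSame",
    "BatchNorm",
    "GRU",
    "BiGRU",
    "Dropout",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "concat",
    "stack_time",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        g = np.asarray(grad, dtype=self.data.dtype)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if self.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_pool(self, pool: tuple):
        """Non-overlapping max pooling over axes 1..len(pool); remainders dropped.

        Gradient is split evenly among tied maxima (a valid subgradient)."""
        x = self.data
        B = x.shape[0]
        spatial = x.shape[1:1 + len(pool)]
        chan = x.shape[1 + len(pool):]
        trimmed = tuple((s // p) * p for s, p in zip(spatial, pool))
        sl = (slice(None),) + tuple(slice(0, t) for t in trimmed)
        xt = x[sl]
        new_shape = (B,)
        for t, p in zip(trimmed, pool):
            new_shape += (t // p, p)
        new_shape += chan
        xr = xt.reshape(new_shape)
        pool_axes = tuple(2 + 2 * i for i in range(len(pool)))
        out_data = xr.max(axis=pool_axes)

        expand = out_data
        for ax in pool_axes:
            expand = np.expand_dims(expand, ax)
        mask = (xr == expand)
        counts = mask.sum(axis=pool_axes, keepdims=True)

        def bwd(g):
            if not self.requires_grad:
                return
            gg = g
            for ax in pool_axes:
                gg = np.expand_dims(gg, ax)
            gr = (mask * (gg / counts)).reshape(xt.shape)
            full = np.zeros_like(x)
            full[sl] = gr
            self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bwd)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def stack_time(tensors) -> Tensor:
    """Stack per-step (B, D) tensors into (B, T, D)."""
    return concat([t.reshape(t.shape[0], 1, t.shape[1]) for t in tensors], axis=1)


def conv_same(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2D correlation.

    x: (B, T, F, Cin); W: (kh, kw, Cin, Cout); b: (Cout,) -> (B, T, F, Cout).
    """
    xd, Wd = x.data, W.data
    B, T, F, Ci = xd.shape
    kh, kw, _, Co = Wd.shape
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    pb, pr = kh - 1 - pt, kw - 1 - pl
    xp = np.pad(xd, ((0, 0), (pt, pb), (pl, pr), (0, 0)))

    # im2col keeps BLAS efficient when the input has few channels (the
    # k*k*Ci inner dimension would otherwise be tiny per offset); with many
    # channels the per-offset matmuls are already large, and skipping the
    # column matrix saves its memory traffic.
    use_im2col = Ci * kh * kw <= 64 and kh * kw > 1
    cols = None
    if use_im2col:
        cols = np.empty((B * T * F, kh * kw * Ci), dtype=xd.dtype)
        col = 0
        for i in range(kh):
            for j in range(kw):
                cols[:, col:col + Ci] = xp[:, i:i + T, j:j + F, :].reshape(-1, Ci)
                col += Ci
        out_data = (cols @ Wd.reshape(-1, Co)).reshape(B, T, F, Co)
    else:
        out_data = np.zeros((B, T, F, Co), dtype=xd.dtype)
        for i in range(kh):
            for j in range(kw):
                out_data += xp[:, i:i + T, j:j + F, :] @ Wd[i, j]
    out_data += b.data

    def bwd(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        gf = g.reshape(-1, Co)
        if W.requires_grad:
            if cols is not None:
                W._accumulate((cols.T @ gf).reshape(kh, kw, Ci, Co))
            else:
                dW = np.zeros_like(Wd)
                for i in range(kh):
                    for j in range(kw):
                        patch = xp[:, i:i + T, j:j + F, :].reshape(-1, Ci)
                        dW[i, j] = patch.T @ gf
                W._accumulate(dW)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            if cols is not None:
                dcols = gf @ Wd.reshape(-1, Co).T
                col = 0
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + T, j:j + F, :] += \
                            dcols[:, col:col + Ci].reshape(B, T, F, Ci)
                        col += Ci
            else:
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i:i + T, j:j + F, :] += g @ Wd[i, j].T
            x._accumulate(dxp[:, pt:pt + T, pl:pl + F, :])

    return Tensor(out_data, parents=(x, W, b), backward=bwd)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on a plain array (inference path)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean cross-entropy with a fused, stable softmax."""
    z = logits.data
    labels = np.asarray(labels, dtype=np.int64)
    zmax = z.max(axis=1, keepdims=True)
    zs = z - zmax
    lse = np.log(np.exp(zs).sum(axis=1, keepdims=True))
    logp = zs - lse
    n = z.shape[0]
    if class_weights is None:
        w = np.ones(n, dtype=z.dtype)
    else:
        w = np.asarray(class_weights, dtype=z.dtype)[labels]
    wsum = w.sum()
    loss = -(w * logp[np.arange(n), labels]).sum() / wsum

    def bwd(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(g * (w[:, None] * p) / wsum)

    return Tensor(np.asarray(loss, dtype=z.dtype), parents=(logits,), backward=bwd)


# ---------------------------------------------------------------------------
# layers


class Module:
    """Base class: parameter discovery plus a train/eval mode flag."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train_mode(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    training = False


def glorot(rng: np.random.Generator, shape, dtype=np.float32) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = Tensor(glorot(rng, (n_in, n_out), dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv2dSame(Module):
    """Same-padded 2D convolution on (B, T, F, Cin)."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.W = Tensor(glorot(rng, (kh, kw, c_in, c_out), dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_same(x, self.W, self.b)


class Conv1dSame(Module):
    """Same-padded 1D convolution on (B, T, Cin), via a (k, 1) 2D kernel."""

    def __init__(self, k: int, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = Tensor(glorot(rng, (k, 1, c_in, c_out), dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        y = conv_same(x.reshape(B, T, 1, C), self.W, self.b)
        return y.reshape(B, T, y.shape[-1])


class BatchNorm(Module):
    """Batch normalization over all axes except the channel (last) axis.

    Batch statistics during training; frozen running averages at inference.
    """

    def __init__(self, n_chan: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(n_chan, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_chan, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n_chan, dtype=dtype)
        self.running_var = np.ones(n_chan, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes)
            xc = x - mu.reshape(*([1] * (x.ndim - 1)), -1)
            var = (xc * xc).mean(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu.data)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.data)
            std = (var + self.eps).sqrt()
            xn = xc * _reciprocal(std.reshape(*([1] * (x.ndim - 1)), -1))
        else:
            mu = self.running_mean
            std = np.sqrt(self.running_var + self.eps)
            xn = (x - mu) * Tensor(1.0 / std)
        return xn * self.gamma + self.beta


def _reciprocal(t: Tensor) -> Tensor:
    out_data = 1.0 / t.data

    def bwd(g):
        if t.requires_grad:
            t._accumulate(-g * out_data * out_data)

    return Tensor(out_data, parents=(t,), backward=bwd)


class GRU(Module):
    """Unidirectional gated recurrent unit, unrolled over the time axis."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.n_hidden = n_hidden
        self.Wz = Dense(n_in, n_hidden, rng, dtype)
        self.Uz = Tensor(glorot(rng, (n_hidden, n_hidden), dtype), requires_grad=True)
        self.Wr = Dense(n_in, n_hidden, rng, dtype)
        self.Ur = Tensor(glorot(rng, (n_hidden, n_hidden), dtype), requires_grad=True)
        self.Wn = Dense(n_in, n_hidden, rng, dtype)
        self.Un = Tensor(glorot(rng, (n_hidden, n_hidden), dtype), requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False):
        B, T, D = x.shape
        # input projections for all steps at once; the loop only carries
        # the recurrent matmuls
        flat = x.reshape(B * T, D)
        xz = self.Wz(flat).reshape(B, T, self.n_hidden)
        xr = self.Wr(flat).reshape(B, T, self.n_hidden)
        xn = self.Wn(flat).reshape(B, T, self.n_hidden)
        h = Tensor(np.zeros((B, self.n_hidden), dtype=x.data.dtype))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outputs = [None] * T
        for t in order:
            z = (xz[:, t, :] + h @ self.Uz).sigmoid()
            r = (xr[:, t, :] + h @ self.Ur).sigmoid()
            n = (xn[:, t, :] + (r * h) @ self.Un).tanh()
            h = (1.0 - z) * n + z * h
            outputs[t] = h
        return stack_time(outputs)


class BiGRU(Module):
    """Bidirectional GRU; forward and backward states concatenated per step."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.fwd = GRU(n_in, n_hidden, rng, dtype)
        self.bwd = GRU(n_in, n_hidden, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=-1)


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
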