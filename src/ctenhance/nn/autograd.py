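"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the primitives the noise-estimation and enhancement
networks need: 2-D convolution, batch normalization, 2x2 max-pooling,
global average pooling, fully-connected layers, channel concatenation,
sub-pixel rearrangement, ReLU/sigmoid, and the scalar losses. Tensors
carry a tape of parent closures; ``backward`` walks the tape in reverse
topological order. Float64 throughout for deterministic, well-conditioned
gradients on CPU.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / data preparation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _make(data, parents, backward):
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g, dtype=DTYPE)
    else:
        t.grad = t.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _make(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def backward(g):
        _accum(a, g * s)

    return _make(a.data * s, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500.0, 500.0)))

    def backward(g):
        _accum(a, g * y * (1.0 - y))

    return _make(y, (a,), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate NCHW tensors along the channel axis."""
    sizes = [t.data.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            _accum(t, g[:, lo:hi])

    return _make(out_data, tuple(tensors), backward)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Sub-pixel rearrangement (N, C*r^2, H, W) -> (N, C, rH, rW).

    Row-major convention: out[c, r*h+dy, r*w+dx] = in[c*r^2 + dy*r + dx, h, w].
    """
    r = int(r)
    if r < 1:
        raise ValueError("scale factor must be >= 1")
    N, Crr, H, W = x.data.shape
    if Crr % (r * r) != 0:
        raise ValueError(
            f"channel count {Crr} not divisible by r^2 = {r * r}"
        )
    C = Crr // (r * r)
    out_data = (
        x.data.reshape(N, C, r, r, H, W)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(N, C, H * r, W * r)
    )

    def backward(g):
        gx = (
            g.reshape(N, C, H, r, W, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(N, Crr, H, W)
        )
        _accum(x, gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling / normalization / linear
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1, symmetric zero padding.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Cw, kh, kw = wd.shape
    if Cw != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    p = int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho = H + 2 * p - kh + 1
    Wo = W + 2 * p - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: kernel larger than padded input")
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    Wm = wd.reshape(O, -1)
    out = cols @ Wm.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
        if w.requires_grad or w._parents:
            _accum(w, (gm.T @ cols).reshape(O, C, kh, kw))
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, gm.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = (gm @ Wm).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + Ho, j:j + Wo] += dcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            _accum(x, dxp[:, :, p:p + H, p:p + W] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Requires even spatial dims."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2 requires even spatial dims, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    xr = (
        x.data.reshape(N, C, Ho, 2, Wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, Ho, Wo, 4)
    )
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        g4 = np.zeros((N, C, Ho, Wo, 4), dtype=DTYPE)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = (
            g4.reshape(N, C, Ho, Wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        _accum(x, gx)

    return _make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Average over the full spatial extent: (N, C, H, W) -> (N, C)."""
    N, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        _accum(x, np.broadcast_to(g[:, :, None, None] / (H * W), (N, C, H, W)))

    return _make(out_data, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, F); w: (O, F); b: (O,)."""
    out_data = x.data @ w.data.T + b.data

    def backward(g):
        if w.requires_grad or w._parents:
            _accum(w, g.T @ x.data)
        if b.requires_grad or b._parents:
            _accum(b, g.sum(axis=0))
        if x.requires_grad or x._parents:
            _accum(x, g @ w.data)

    return _make(out_data, (x, w, b), backward)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running statistics
    are updated in place; in evaluation mode the frozen running statistics
    are used, making inference deterministic.
    """
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        m = N * H * W
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad or gamma._parents:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or x._parents):
            return
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            m = N * H * W
            sum_g = gxhat.sum(axis=(0, 2, 3))
            sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3))
            gx = (
                inv_std[None, :, None, None]
                / m
                * (m * gxhat - sum_g[None, :, None, None] - xhat * sum_gx[None, :, None, None])
            )
        else:
            gx = gxhat * inv_std[None, :, None, None]
        _accum(x, gx)

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    labels = np.asarray(labels)
    N = logits.data.shape[0]
    p = softmax(logits.data)
    eps = 1e-12
    loss = -np.log(p[np.arange(N), labels] + eps).mean()

    def backward(g):
        gl = p.copy()
        gl[np.arange(N), labels] -= 1.0
        _accum(logits, g * gl / N)

    return _make(loss, (logits,), backward)


def scaled_sq_error(a: Tensor, b: Tensor, denom: float) -> Tensor:
    """sum((a-b)^2) / denom, as a scalar tensor."""
    diff = a.data - b.data
    out = float((diff * diff).sum() / denom)

    def backward(g):
        gd = g * 2.0 * diff / denom
        _accum(a, gd)
        _accum(b, -gd)

    return _make(out, (a, b), backward)
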