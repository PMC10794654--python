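"""Minimal reverse-mode autodiff on NumPy arrays.

Implements exactly the operations the U-Net family needs — 2-D convolution
(stride 1, im2col + GEMM), max pooling, nearest-neighbour upsampling, ReLU,
sigmoid, channel concatenation and broadcast multiply — on float32 **NHWC**
tensors (channels last, so im2col reduces to contiguous block copies and
the three convolution GEMMs run at full BLAS speed on one core).  Each op
records a backward closure; ``Tensor.backward`` replays them in reverse
topological order.  There is no stride/dilation generality: the engine is
sized to the networks in :mod:`oktopo.models`, not a general framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2d",
    "upsample_nearest",
    "relu",
    "sigmoid",
    "concat",
    "mul",
    "global_maxpool",
    "batchnorm",
    "backward_multi",
]


class Tensor:
    """An array node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of a seed ``grad`` (default: ones) into every
        ``requires_grad`` ancestor.  Must be called once per tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _im2col(xp: np.ndarray, kh: int, kw: int, ho: int, wo: int) -> np.ndarray:
    """im2col for NHWC input: (N,Hp,Wp,C) → (N·Ho·Wo, kh·kw·C)."""
    n, _, _, c = xp.shape
    if kh == kw == 1:
        return xp.reshape(n * ho * wo, c)
    cols = np.empty((n, ho, wo, kh, kw, c), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i : i + ho, j : j + wo, :]
    return cols.reshape(n * ho * wo, kh * kw * c)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """Stride-1 cross-correlation of ``x`` (N,H,W,C) with ``w`` (kh,kw,C,Cout)."""
    xd = x.data
    n, h, wid, c = xd.shape
    kh, kw, cin, cout = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {cin}")
    xp = np.pad(xd, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else xd
    ho = h + 2 * pad - kh + 1
    wo = wid + 2 * pad - kw + 1
    cols = _im2col(xp, kh, kw, ho, wo)
    out = (cols @ w.data.reshape(kh * kw * cin, cout)).reshape(n, ho, wo, cout)
    if b is not None:
        out += b.data

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g: np.ndarray) -> None:
        g2d = g.reshape(n * ho * wo, cout)
        if b is not None and b.requires_grad:
            _accum(b, g2d.sum(axis=0))
        if w.requires_grad:
            _accum(w, (cols.T @ g2d).reshape(kh, kw, cin, cout))
        if x.requires_grad or x._parents:
            # input gradient = full correlation of g with the flipped,
            # channel-transposed kernel (one GEMM, no scatter-add)
            wf = w.data[::-1, ::-1].transpose(0, 1, 3, 2).reshape(kh * kw * cout, cin)
            ph, pw = kh - 1 - pad, kw - 1 - pad
            pg = np.pad(g, ((0, 0), (ph, ph), (pw, pw), (0, 0))) if (ph or pw) else g
            gcols = _im2col(pg, kh, kw, h, wid)
            _accum(x, (gcols @ wf).reshape(n, h, wid, cin))

    return Tensor(out, parents=parents, backward=bwd)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k×k max pooling with stride k; spatial dims must divide by k."""
    n, h, w, c = x.data.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: {h}x{w} not divisible by {k}")
    hk, wk = h // k, w // k
    xr = (
        x.data.reshape(n, hk, k, wk, k, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, hk, wk, k * k, c)
    )
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def bwd(g: np.ndarray) -> None:
        dxr = np.zeros((n, hk, wk, k * k, c), dtype=np.float32)
        np.put_along_axis(dxr, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        dx = (
            dxr.reshape(n, hk, wk, k, k, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )
        _accum(x, dx)

    return Tensor(out, parents=(x,), backward=bwd)


def upsample_nearest(x: Tensor, s: int = 2) -> Tensor:
    n, h, w, c = x.data.shape
    out = x.data.repeat(s, axis=1).repeat(s, axis=2)

    def bwd(g: np.ndarray) -> None:
        _accum(x, g.reshape(n, h, s, w, s, c).sum(axis=(2, 4)))

    return Tensor(out, parents=(x,), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0.0)

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * mask)

    return Tensor(out, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    xd = np.clip(x.data, -60.0, 60.0)
    y = 1.0 / (1.0 + np.exp(-xd))

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _accum(t, g[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward=bwd)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, sz in enumerate(shape):
        if sz == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bwd(g: np.ndarray) -> None:
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out, parents=(a, b), backward=bwd)


def global_maxpool(x: Tensor) -> Tensor:
    """Max over all spatial positions → (N, 1, 1, C)."""
    n, h, w, c = x.data.shape
    flat = x.data.reshape(n, h * w, c)
    idx = flat.argmax(axis=1)
    out = np.take_along_axis(flat, idx[:, None, :], axis=1).reshape(n, 1, 1, c)

    def bwd(g: np.ndarray) -> None:
        dflat = np.zeros((n, h * w, c), dtype=np.float32)
        np.put_along_axis(dflat, idx[:, None, :], g.reshape(n, 1, c), axis=1)
        _accum(x, dflat.reshape(n, h, w, c))

    return Tensor(out, parents=(x,), backward=bwd)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    momentum: float = 0.1,
    eps: float = 1e-5,
    training: bool = False,
) -> Tensor:
    """Per-channel batch normalisation over the (N, H, W) axes of NHWC.

    In training mode batch statistics are used and the running buffers are
    updated in place; in inference mode the running buffers are used.
    """
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 1, 2))
        var = xd.var(axis=(0, 1, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out = gamma.data * xhat + beta.data

    def bwd(g: np.ndarray) -> None:
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 1, 2)))
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            gg = g * gamma.data
            if training:
                dx = inv * (
                    gg
                    - gg.mean(axis=(0, 1, 2))
                    - xhat * (gg * xhat).mean(axis=(0, 1, 2))
                )
            else:
                dx = gg * inv
            _accum(x, dx.astype(np.float32))

    return Tensor(out, parents=(x, gamma, beta), backward=bwd)


def backward_multi(heads, seeds) -> None:
    """Backpropagate several seed gradients through a shared tape in one pass.

    Deep-supervision losses produce one seed gradient per head; running
    ``backward`` per head would double-count shared subgraphs, so a joint
    root is built whose backward deposits every seed at once.
    """
    heads = list(heads)
    seeds = [np.asarray(s, dtype=np.float32) for s in seeds]
    if len(heads) != len(seeds):
        raise ValueError("one seed gradient per head required")

    def bwd(_g: np.ndarray) -> None:
        for h, s in zip(heads, seeds):
            _accum(h, s)

    root = Tensor(np.zeros(()), parents=tuple(heads), backward=bwd)
    root.backward(np.zeros(()))
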