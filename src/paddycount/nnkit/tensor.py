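"""Minimal reverse-mode autodiff over numpy arrays.

A deliberately small tape: each ``Tensor`` records its parents and a closure
that maps the upstream gradient to per-parent contributions. Only the
operations the counting network needs are provided (grouped 2-D convolution,
batch normalization, ReLU/swish, unpadded average pooling, bilinear 2x
upsampling, channel concatenation, log-softmax and the two losses). All
arithmetic is float32; convolution is im2col + BLAS matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "relu",
    "swish",
    "add",
    "concat",
    "conv2d",
    "avg_pool2d",
    "upsample_bilinear2x",
    "batch_norm2d",
    "log_softmax",
    "softmax_cross_entropy_map",
    "l1_loss",
]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fn")

    def __init__(self, data, requires_grad=False, _parents=(), _grad_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._grad_fn = _grad_fn

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() is defined for scalar outputs only")
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
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._grad_fn is None:
                continue
            grads = t._grad_fn(t.grad)
            for p, g in zip(t._parents, grads):
                if g is None or not p.requires_grad:
                    continue
                p.grad = g if p.grad is None else p.grad + g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, _parents=(x,), _grad_fn=lambda g: (g * mask,))


def swish(x: Tensor) -> Tensor:
    """x * sigmoid(x), the activation used in mixed-kernel depthwise blocks."""
    x = _as_tensor(x)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out = x.data * sig

    def grad_fn(g):
        return (g * (sig * (1.0 + x.data * (1.0 - sig))),)

    return Tensor(out, _parents=(x,), _grad_fn=grad_fn)


def add(x: Tensor, y: Tensor) -> Tensor:
    x, y = _as_tensor(x), _as_tensor(y)
    if x.data.shape != y.data.shape:
        raise ValueError(f"add: shape mismatch {x.data.shape} vs {y.data.shape}")
    return Tensor(x.data + y.data, _parents=(x, y), _grad_fn=lambda g: (g, g))


def concat(xs: list[Tensor], axis: int = 1) -> Tensor:
    xs = [_as_tensor(x) for x in xs]
    sizes = [x.data.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([x.data for x in xs], axis=axis), _parents=tuple(xs), _grad_fn=grad_fn)


def _conv_group(cols, w_flat):
    # cols: (N*Ho*Wo, Cg*KH*KW); w_flat: (Og, Cg*KH*KW)
    return cols @ w_flat.T


def conv2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0, groups: int = 1
) -> Tensor:
    """Grouped 2-D convolution (cross-correlation), NCHW layout."""
    x, w = _as_tensor(x), _as_tensor(w)
    N, C, H, W = x.data.shape
    O, Cg, KH, KW = w.data.shape
    if C != Cg * groups or O % groups:
        raise ValueError(f"conv2d: channels {C} / weight {w.data.shape} / groups {groups} mismatch")
    Og = O // groups
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    Ho = (xp.shape[2] - KH) // stride + 1
    Wo = (xp.shape[3] - KW) // stride + 1
    win = sliding_window_view(xp, (KH, KW), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, KH, KW) -> (N, Ho, Wo, C, KH, KW), contiguous for matmul
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    out = np.empty((N, O, Ho, Wo), dtype=np.float32)
    wf = w.data.reshape(O, Cg * KH * KW)
    for g in range(groups):
        cg = cols[:, :, :, g * Cg : (g + 1) * Cg].reshape(N * Ho * Wo, Cg * KH * KW)
        og = _conv_group(cg, wf[g * Og : (g + 1) * Og])
        out[:, g * Og : (g + 1) * Og] = og.reshape(N, Ho, Wo, Og).transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1)

    def grad_fn(gout):
        gf = gout.transpose(0, 2, 3, 1)  # N,Ho,Wo,O
        dw = np.empty_like(w.data)
        dcols = np.empty_like(cols)
        for g in range(groups):
            gg = np.ascontiguousarray(gf[..., g * Og : (g + 1) * Og]).reshape(N * Ho * Wo, Og)
            cg = cols[:, :, :, g * Cg : (g + 1) * Cg].reshape(N * Ho * Wo, Cg * KH * KW)
            dw[g * Og : (g + 1) * Og] = (gg.T @ cg).reshape(Og, Cg, KH, KW)
            dcols[:, :, :, g * Cg : (g + 1) * Cg] = (gg @ wf[g * Og : (g + 1) * Og]).reshape(
                N, Ho, Wo, Cg, KH, KW
            )
        dxp = np.zeros_like(xp)
        dct = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,KH,KW
        for i in range(KH):
            for j in range(KW):
                dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dct[
                    :, :, :, :, i, j
                ]
        dx = dxp[:, :, padding : padding + H, padding : padding + W] if padding else dxp
        db = gout.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, _parents=parents, _grad_fn=grad_fn)


def avg_pool2d(x: Tensor, kernel: int, stride: int = 1) -> Tensor:
    """Unpadded average pooling; output dims shrink by (kernel - 1) / stride."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if H < kernel or W < kernel:
        raise ValueError(f"avg_pool2d: spatial dims {(H, W)} smaller than kernel {kernel}")
    win = sliding_window_view(x.data, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    out = win.mean(axis=(4, 5), dtype=np.float32)
    Ho, Wo = out.shape[2], out.shape[3]

    def grad_fn(g):
        dx = np.zeros_like(x.data)
        gk = g / (kernel * kernel)
        for i in range(kernel):
            for j in range(kernel):
                dx[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += gk
        return (dx,)

    return Tensor(out, _parents=(x,), _grad_fn=grad_fn)


_INTERP_CACHE: dict[int, np.ndarray] = {}


def _interp_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) bilinear interpolation matrix, half-pixel-center convention."""
    if n not in _INTERP_CACHE:
        src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, n - 1)
        i1 = np.clip(i0 + 1, 0, n - 1)
        w1 = np.clip(src - i0, 0.0, 1.0)
        m = np.zeros((2 * n, n), dtype=np.float32)
        m[np.arange(2 * n), i0] += 1.0 - w1
        m[np.arange(2 * n), i1] += w1
        _INTERP_CACHE[n] = m
    return _INTERP_CACHE[n]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling (half-pixel centers)."""
    x = _as_tensor(x)
    _, _, H, W = x.data.shape
    mh, mw = _interp_matrix(H), _interp_matrix(W)
    out = (mh @ x.data) @ mw.T

    def grad_fn(g):
        return ((mh.T @ g) @ mw,)

    return Tensor(out, _parents=(x,), _grad_fn=grad_fn)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization with running statistics.

    In training mode, batch statistics over (N, H, W) are used and the running
    buffers are updated in place; in eval mode the running buffers are used.
    """
    x = _as_tensor(x)
    C = x.data.shape[1]
    shape = (1, C, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def grad_fn(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gs = g * gamma.data.reshape(shape)
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            mean_gs = gs.mean(axis=(0, 2, 3)).reshape(shape)
            mean_gs_xhat = (gs * xhat).mean(axis=(0, 2, 3)).reshape(shape)
            dx = inv_std.reshape(shape) * (gs - mean_gs - xhat * mean_gs_xhat)
        else:
            dx = gs * inv_std.reshape(shape)
        return (dx.astype(np.float32), dgamma, dbeta)

    return Tensor(out, _parents=(x, gamma, beta), _grad_fn=grad_fn)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - logz

    def grad_fn(g):
        p = np.exp(out)
        return (g - p * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, _parents=(x,), _grad_fn=grad_fn)


def softmax_cross_entropy_map(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean cross-entropy over a class-logit map.

    ``logits`` is (N, C, H, W); ``target`` an integer (N, H, W) class map.
    Returns the scalar mean over all cells of -log p(cell, target class).
    """
    logits = _as_tensor(logits)
    target = np.asarray(target)
    if logits.data.shape[0] != target.shape[0] or logits.data.shape[2:] != target.shape[1:]:
        raise ValueError(
            f"cross-entropy grids misaligned: logits {logits.data.shape} vs target {target.shape}"
        )
    lp = log_softmax(logits, axis=1)
    n, _, h, w = lp.data.shape
    ni, hi, wi = np.ogrid[:n, :h, :w]
    picked = lp.data[ni, target, hi, wi]
    out = -picked.mean()

    def grad_fn(g):
        glp = np.zeros_like(lp.data)
        glp[ni, target, hi, wi] = -g / picked.size
        return (glp,)

    loss = Tensor(out, _parents=(lp,), _grad_fn=grad_fn)
    return loss


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute difference over all cells."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float32)
    if pred.data.shape != target.shape:
        raise ValueError(f"l1 grids misaligned: {pred.data.shape} vs {target.shape}")
    diff = pred.data - target
    out = np.abs(diff).mean()

    def grad_fn(g):
        return (g * np.sign(diff) / diff.size,)

    return Tensor(out, _parents=(pred,), _grad_fn=grad_fn)
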