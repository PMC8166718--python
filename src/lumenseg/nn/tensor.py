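"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small engine: float32 tensors, a handful of ops (dense and
convolutional), and a topological-sort backward pass.  Every op caches only
what its backward needs.  Feature maps are laid out channels-last (NHWC),
which keeps im2col gathers cache-friendly, and convolutions are im2col +
BLAS matmul - the fastest route on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "sigmoid", "add", "concat_channels", "pad2d",
           "conv2d", "conv_transpose2d_2x2", "maxpool2d_2x2", "batch_norm2d",
           "soft_dice_loss"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            if t.requires_grad or t._parents:
                t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _node(data, parents, backward):
    track = any(p.requires_grad or p._parents for p in parents)
    if not track:
        return Tensor(data)
    return Tensor(data, _parents=tuple(parents), _backward=backward)


def _accum(t, g):
    if t.grad is not None:
        t.grad += g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        _accum(x, g * mask)

    return _node(x.data * mask, [x], backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g):
        _accum(x, g * out * (1.0 - out))

    return _node(out, [x], backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch {a.data.shape} vs {b.data.shape}")

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _node(a.data + b.data, [a, b], backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two NHWC tensors along the channel axis."""
    ca = a.data.shape[3]

    def backward(g):
        _accum(a, g[..., :ca])
        _accum(b, g[..., ca:])

    return _node(np.concatenate([a.data, b.data], axis=3), [a, b], backward)


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two spatial dimensions of an NHWC tensor."""
    data = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))

    def backward(g):
        _accum(x, g[:, pad:-pad, pad:-pad, :])

    return _node(data, [x], backward)


def _im2col(x, kh, kw, stride, pad):
    """NHWC patches flattened to (N*Ho*Wo, kh*kw*C)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]          # (N, Ho, Wo, C, kh, kw)
    n, ho, wo = win.shape[:3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * ho * wo, kh * kw * x.shape[3]), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,H,W,C); w: (F,C,kh,kw); b: (F,)."""
    n, h, wd, c = x.data.shape
    f, _, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(-1, f)
    out = cols @ wmat
    out += b.data
    out = out.reshape(n, ho, wo, f)

    def backward(g):
        gmat = g.reshape(-1, f)
        if w.grad is not None:
            gw = (cols.T @ gmat).reshape(kh, kw, c, f)
            w.grad += gw.transpose(3, 2, 0, 1)
        if b.grad is not None:
            b.grad += gmat.sum(axis=0)
        if x.grad is not None:
            gcols = gmat @ wmat.T
            gc = gcols.reshape(n, ho, wo, kh, kw, c)
            hp, wp = h + 2 * pad, wd + 2 * pad
            gxp = np.zeros((n, hp, wp, c), dtype=np.float32)
            for a in range(kh):
                for bb in range(kw):
                    gxp[:, a:a + stride * ho:stride,
                        bb:bb + stride * wo:stride, :] += gc[:, :, :, a, bb, :]
            x.grad += gxp[:, pad:hp - pad, pad:wp - pad, :] if pad else gxp

    return _node(out, [x, w, b], backward)


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution (the classic U-Net up-conv).

    x: (N,H,W,Cin); w: (Cin,Cout,2,2); b: (Cout,). Output (N,2H,2W,Cout).
    Windows do not overlap, so forward/backward are four strided writes.
    """
    n, h, wd, ci = x.data.shape
    co = w.data.shape[1]
    w_ab = np.ascontiguousarray(w.data.transpose(2, 3, 0, 1))  # (2,2,Cin,Cout)
    out = np.empty((n, 2 * h, 2 * wd, co), dtype=np.float32)
    for a in range(2):
        for bb in range(2):
            out[:, a::2, bb::2, :] = x.data @ w_ab[a, bb]
    out += b.data

    def backward(g):
        for a in range(2):
            for bb in range(2):
                gsub = g[:, a::2, bb::2, :]
                if x.grad is not None:
                    x.grad += gsub @ w_ab[a, bb].T
                if w.grad is not None:
                    gw = x.data.reshape(-1, ci).T @ gsub.reshape(-1, co)
                    w.grad[:, :, a, bb] += gw
        if b.grad is not None:
            b.grad += g.reshape(-1, co).sum(axis=0)

    return _node(out, [x, w, b], backward)


def maxpool2d_2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2d_2x2 requires even spatial dims")
    ho, wo = h // 2, w // 2
    xr = x.data.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = np.ascontiguousarray(xr).reshape(n, ho, wo, c, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.grad is None:
            return
        gr = np.zeros((n, ho, wo, c, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x.grad += gr.reshape(n, h, w, c)

    return _node(out, [x], backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization on NHWC; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data
    m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def backward(g):
        if gamma.grad is not None:
            gamma.grad += (g * xhat).sum(axis=(0, 1, 2))
        if beta.grad is not None:
            beta.grad += g.sum(axis=(0, 1, 2))
        if x.grad is None:
            return
        gxhat = g * gamma.data
        if training:
            s1 = gxhat.sum(axis=(0, 1, 2))
            s2 = (gxhat * xhat).sum(axis=(0, 1, 2))
            x.grad += (inv / m) * (m * gxhat - s1 - xhat * s2)
        else:
            x.grad += gxhat * inv

    return _node(out.astype(np.float32), [x, gamma, beta], backward)


def soft_dice_loss(probs: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Differentiable Dice loss 1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps).

    ``probs`` holds per-pixel foreground probabilities; ``target`` is the
    binary ground truth of identical shape.  The smoothing ``eps`` keeps the
    loss defined when both are empty.
    """
    g = np.asarray(target, dtype=np.float32)
    if g.shape != probs.data.shape:
        raise ValueError("probs/target shape mismatch")
    num = 2.0 * float((probs.data * g).sum(dtype=np.float64)) + eps
    den = float(probs.data.sum(dtype=np.float64)) \
        + float(g.sum(dtype=np.float64)) + eps
    loss = 1.0 - num / den

    def backward(gout):
        if probs.grad is not None:
            # d/dp [ -(2*sum(pg)+eps)/(sum(p)+sum(g)+eps) ]
            probs.grad += gout * (num / den ** 2 - 2.0 * g / den)

    return _node(np.float32(loss), [probs], backward)
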