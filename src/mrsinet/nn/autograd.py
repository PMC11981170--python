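"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the 1D networks in this package: tensors with
gradients, a topological-order backward pass, and fused array ops
(matmul, 1D convolution via im2col, batch norm, pooling, activations,
losses).  Float32 by default; gradients accumulate in the data dtype.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "retains_grad",
                 "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.retains_grad = requires_grad and not parents
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def retain_grad(self) -> "Tensor":
        """Keep this intermediate node's gradient after backward()."""
        self.retains_grad = True
        return self

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents and not node.retains_grad:
                node.grad = None  # free intermediate gradients


def _unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original shape."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data, parents=tuple(parents))
    if out.requires_grad:
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))
    return _node(a.data + b.data, (a, b), bw)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(g * s)
    return _node(a.data * s, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)
    return _node(a.data @ b.data, (a, b), bw)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    def bw(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data ** 2))
    return _node(out_data, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)
    return _node(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    def bw(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))
    return _node(out_data, (a,), bw)


def reshape(a: Tensor, shape: Tuple[int, ...]) -> Tensor:
    orig = a.shape
    def bw(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))
    return _node(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes: Tuple[int, ...]) -> Tensor:
    inv = tuple(np.argsort(axes))
    def bw(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))
    return _node(a.data.transpose(axes), (a,), bw)


def flip(a: Tensor, axis: int) -> Tensor:
    def bw(g):
        if a.requires_grad:
            a._accumulate(np.flip(g, axis=axis))
    return _node(np.flip(a.data, axis=axis), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.data.size / out_data.size
    def bw(g):
        if a.requires_grad:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape) / count)
    return _node(out_data, (a,), bw)


def _corr1d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Correlation: out[b,o,l] = sum_{c,k} w[o,c,k] * xpad[b,c,l+k]."""
    B, C, L = x.shape
    O, _, K = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # B,C,Lo,K
    Lo = cols.shape[2]
    colmat = cols.transpose(0, 2, 1, 3).reshape(B * Lo, C * K)
    out = colmat @ w.reshape(O, C * K).T
    return out.reshape(B, Lo, O).transpose(0, 2, 1), colmat


def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           padding: Optional[int] = None) -> Tensor:
    """Same-padding stride-1 cross-correlation of (B, C, L) with (O, C, K)."""
    O, C, K = w.shape
    pad = K // 2 if padding is None else padding
    out_data, colmat = _corr1d(x.data, w.data, pad)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    B, _, Lo = out_data.shape

    def bw(g):
        gm = g.transpose(1, 0, 2).reshape(O, B * Lo)
        if w.requires_grad:
            dw = (gm @ colmat).reshape(O, C, K)
            w._accumulate(dw.astype(w.data.dtype))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)).astype(b.data.dtype))
        if x.requires_grad:
            w_swap = np.flip(w.data, axis=2).transpose(1, 0, 2)  # C,O,K
            dxp, _ = _corr1d(g, w_swap, K - 1)
            lo = K - 1 - pad
            x._accumulate(dxp[:, :, lo:lo + x.shape[2]].astype(x.data.dtype))
    return _node(out_data, tuple(t for t in (x, w, b) if t is not None), bw)


def avg_pool1d(x: Tensor, k: int = 2) -> Tensor:
    B, C, L = x.shape
    if L % k:
        raise ValueError(f"length {L} not divisible by pool size {k}")
    out_data = x.data.reshape(B, C, L // k, k).mean(axis=3)
    def bw(g):
        if x.requires_grad:
            x._accumulate(np.repeat(g / k, k, axis=2))
    return _node(out_data, (x,), bw)


def batch_norm1d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch norm over (B, C, L); updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None]) * inv_std[None, :, None]
    out_data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
    m = x.data.shape[0] * x.data.shape[2]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2)).astype(gamma.data.dtype))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2)).astype(beta.data.dtype))
        if x.requires_grad:
            gxhat = g * gamma.data[None, :, None]
            if training:
                sum_g = gxhat.sum(axis=(0, 2), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
                dx = (gxhat - sum_g / m - xhat * sum_gx / m) \
                    * inv_std[None, :, None]
            else:
                dx = gxhat * inv_std[None, :, None]
            x._accumulate(dx.astype(x.data.dtype))
    return _node(out_data, (x, gamma, beta), bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over all elements of the squared difference (float64 accumulation)."""
    diff = pred.data.astype(np.float64) - np.asarray(target, dtype=np.float64)
    out_data = np.asarray((diff ** 2).mean())
    def bw(g):
        if pred.requires_grad:
            pred._accumulate((g * 2.0 * diff / diff.size).astype(pred.data.dtype))
    return _node(out_data, (pred,), bw)


def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    z = logits.data.astype(np.float64)
    y = np.asarray(target, dtype=np.float64)
    # softplus(z) - y*z, with softplus computed stably
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    out_data = np.asarray(loss.mean())
    p = 1.0 / (1.0 + np.exp(-z))
    def bw(g):
        if logits.requires_grad:
            logits._accumulate((g * (p - y) / y.size).astype(logits.data.dtype))
    return _node(out_data, (logits,), bw)
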