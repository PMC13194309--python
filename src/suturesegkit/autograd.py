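"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the temporal segmentation network on CPU:
a tape of :class:`Tensor` nodes and the handful of primitives the
architecture needs (dilated temporal convolution, 1x1 convolution, ReLU,
dropout, batch normalization, softmax, and a fused segmentation loss).
Sequences are stored channel-major as (C, T) float32 so convolutions reduce
to BLAS matrix products.
"""
from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np


class Tensor:
    """A node on the autodiff tape wrapping a float32 numpy array."""

    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents: tuple = (), bw: Optional[Callable] = None):
        data = np.asarray(data)
        if data.dtype != np.float64:  # float32 by default; float64 kept for
            data = data.astype(np.float32)  # high-precision gradient checks
        self.data = data
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._bw = bw

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += np.asarray(g, dtype=self.data.dtype)

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: sequences can be thousands of nodes deep
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def parameter(array: np.ndarray) -> Tensor:
    return Tensor(array)


# ----------------------------------------------------------------- primitives

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a._accum(g)
        b._accum(g)

    out._bw = bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), (x,))

    def bw(g):
        x._accum(np.where(mask, g, 0.0))

    out._bw = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = Tensor(x.data * keep, (x,))

    def bw(g):
        x._accum(g * keep)

    out._bw = bw
    return out


def conv1x1(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Pointwise temporal convolution: (C_out, C_in) @ (C_in, T) + bias."""
    out = Tensor(W.data @ x.data + b.data[:, None], (x, W, b))

    def bw(g):
        W._accum(g @ x.data.T)
        b._accum(g.sum(axis=1))
        x._accum(W.data.T @ g)

    out._bw = bw
    return out


def conv1d_k3(x: Tensor, W: Tensor, b: Tensor, dilation: int) -> Tensor:
    """Kernel-3 dilated temporal convolution with zero padding.

    x: (C_in, T); W: (C_out, C_in, 3); output (C_out, T).
    """
    C_in, T = x.data.shape
    d = dilation
    xp = np.zeros((C_in, T + 2 * d), dtype=x.data.dtype)
    xp[:, d:d + T] = x.data
    y = (W.data[:, :, 0] @ xp[:, 0:T]
         + W.data[:, :, 1] @ xp[:, d:d + T]
         + W.data[:, :, 2] @ xp[:, 2 * d:2 * d + T]
         + b.data[:, None])
    out = Tensor(y, (x, W, b))

    def bw(g):
        dW = np.empty_like(W.data)
        dW[:, :, 0] = g @ xp[:, 0:T].T
        dW[:, :, 1] = g @ xp[:, d:d + T].T
        dW[:, :, 2] = g @ xp[:, 2 * d:2 * d + T].T
        W._accum(dW)
        b._accum(g.sum(axis=1))
        dxp = np.zeros_like(xp)
        dxp[:, 0:T] += W.data[:, :, 0].T @ g
        dxp[:, d:d + T] += W.data[:, :, 1].T @ g
        dxp[:, 2 * d:2 * d + T] += W.data[:, :, 2].T @ g
        x._accum(dxp[:, d:d + T])

    out._bw = bw
    return out


def concat_channels(parts: Sequence[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=0), tuple(parts))
    sizes = [p.data.shape[0] for p in parts]

    def bw(g):
        off = 0
        for p, s in zip(parts, sizes):
            p._accum(g[off:off + s])
            off += s

    out._bw = bw
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel (class) axis of a (C, T) tensor."""
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=0, keepdims=True)
    out = Tensor(s, (x,))

    def bw(g):
        x._accum(s * (g - (g * s).sum(axis=0, keepdims=True)))

    out._bw = bw
    return out


def batchnorm_channels(x: Tensor, gamma: Tensor, beta: Tensor,
                       running_mean: np.ndarray, running_var: np.ndarray,
                       training: bool, momentum: float = 0.1,
                       eps: float = 1e-5) -> Tensor:
    """1-D batch normalization per channel over the time axis.

    In training mode the statistics of the current sequence are used and the
    running statistics updated in place; in evaluation mode the frozen
    running statistics are applied.
    """
    if training:
        mean = x.data.mean(axis=1, keepdims=True)
        var = x.data.var(axis=1, keepdims=True)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean[:, 0]
        running_var *= (1.0 - momentum)
        running_var += momentum * var[:, 0]
    else:
        mean = running_mean[:, None].astype(x.data.dtype)
        var = running_var[:, None].astype(x.data.dtype)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out = Tensor(gamma.data[:, None] * xhat + beta.data[:, None],
                 (x, gamma, beta))
    T = x.data.shape[1]

    def bw(g):
        gamma._accum((g * xhat).sum(axis=1))
        beta._accum(g.sum(axis=1))
        gx = g * gamma.data[:, None] * inv
        if training:
            gx = gx - gx.mean(axis=1, keepdims=True) \
                 - xhat * (gx * xhat).mean(axis=1, keepdims=True)
        x._accum(gx)

    out._bw = bw
    return out


def mstcn_stage_loss(logits: Tensor, labels: np.ndarray,
                     lambda_smooth: float, tau: float) -> Tensor:
    """Frame-mean cross-entropy plus truncated-MSE temporal smoothing.

    The smoothing term is the mean over frames t>=1 and classes of
    ``min(tau, |log p_t - log p_{t-1}|)^2`` with the previous-frame
    log-probability treated as a constant for gradients.
    """
    C, T = logits.data.shape
    z = logits.data.astype(np.float64)
    z = z - z.max(axis=0, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=0, keepdims=True))
    logp = z - logsumexp
    p = np.exp(logp)
    ce = -logp[labels, np.arange(T)].mean()

    loss = ce
    dlogp = np.zeros_like(logp)  # gradient wrt logp from the smoothing term
    if T > 1 and lambda_smooth > 0.0:
        diff = logp[:, 1:] - logp[:, :-1]
        clipped = np.clip(diff, -tau, tau)
        tmse = float((clipped ** 2).mean())
        loss = ce + lambda_smooth * tmse
        inside = (np.abs(diff) < tau)
        dlogp[:, 1:] = lambda_smooth * 2.0 * clipped * inside / clipped.size

    out = Tensor(np.asarray(loss, dtype=logits.data.dtype), (logits,))

    def bw(g):
        gf = float(g)
        # cross-entropy: (p - onehot)/T ; smoothing: through log-softmax
        dz = p.copy() / T
        dz[labels, np.arange(T)] -= 1.0 / T
        dz += dlogp - p * dlogp.sum(axis=0, keepdims=True)
        logits._accum(gf * dz)

    out._bw = bw
    return out


def sum_scalars(parts: Sequence[Tensor]) -> Tensor:
    out = Tensor(np.sum([p.data for p in parts]), tuple(parts))

    def bw(g):
        for p in parts:
            p._accum(g)

    out._bw = bw
    return out


class Adam:
    """Adam optimizer with the standard default moments."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


__all__ = [
    "Tensor", "parameter", "add", "relu", "dropout", "conv1x1", "conv1d_k3",
    "concat_channels", "softmax_channels", "batchnorm_channels",
    "mstcn_stage_loss", "sum_scalars", "Adam",
]
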