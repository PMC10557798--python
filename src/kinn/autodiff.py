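"""Minimal reverse-mode automatic differentiation over numpy arrays.

Purpose-built for the small differentiable models in this package: dense
and single-filter convolutional layers, log-sum-exp King-Altman layers, a
spectral (eigenvalue) output, recurrent and attention blocks.  Supports
broadcasting for elementwise ops, batched matmul, and custom primitives
(see :func:`kinn.model.slow_eigen_rate_layer`).

Usage::

    w = Tensor(np.zeros((3, 2)), requires_grad=True)
    y = (x @ w).tanh().sum()
    y.backward()
    w.grad  # dL/dw
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph machinery ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def back(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * p * self.data ** (p - 1)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def back(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = g[..., None] * b              # (..., k)
                elif a.ndim == 1:
                    ga = (b @ g[..., None])[..., 0]    # batch dims summed below
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(ga)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    gb = a * g
                elif a.ndim == 1:
                    gb = a[:, None] * g[..., None, :]  # (..., k, m)
                elif b.ndim == 1:
                    gb = (a * g[..., None]).reshape(-1, a.shape[-1]).sum(0)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(gb)
        out._backward = back
        return out

    # -- nonlinearities -----------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - val**2))
        return out

    def sigmoid(self):
        val = np.where(self.data >= 0,
                       1.0 / (1.0 + np.exp(-np.abs(self.data))),
                       np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val * (1 - val))
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out._backward = lambda g: self.requires_grad and self._accum(g * sig)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        out = Tensor(np.maximum(self.data, lo), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        ax = axes or None
        out = Tensor(self.data.transpose(ax), parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(inv) if inv is not None else g.transpose()
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        def back(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = back
        return out

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        """Numerically stable log-sum-exp along one axis.

        The max is treated as a constant shift, which leaves the gradient
        (a softmax) exact.
        """
        m = np.max(self.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        shifted = self - Tensor(m)
        res = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        return res if keepdims else _squeeze(res, axis)


def _squeeze(t: Tensor, axis: int) -> Tensor:
    shape = list(t.data.shape)
    axis = axis % len(shape)
    del shape[axis]
    return t.reshape(*shape)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])
    out._backward = back
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.data.shape)
        shape.insert(axis % (t.data.ndim + 1), 1)
        expanded.append(t.reshape(*shape))
    return concatenate(expanded, axis=axis)


def conv1d(x: Tensor, w: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """'Same'-padded 1-D convolution.

    ``x``: (n, L, C_in); ``w``: (kernel, C_in, C_out); returns (n, L, C_out).
    """
    n, L, cin = x.data.shape
    k, _, cout = w.data.shape
    span = (k - 1) * dilation
    pad_lo = span // 2
    xp = np.zeros((n, L + span, cin))
    xp[:, pad_lo:pad_lo + L] = x.data
    # windows: (n, L, k, cin)
    idx = np.arange(L)[:, None] + dilation * np.arange(k)[None, :]
    windows = xp[:, idx]                       # (n, L, k, cin)
    val = np.einsum("nlkc,kco->nlo", windows, w.data)
    parents = (x, w) + ((bias,) if bias is not None else ())
    if bias is not None:
        val = val + bias.data
    out = Tensor(val, parents=parents)
    def back(g):
        if w.requires_grad:
            w._accum(np.einsum("nlkc,nlo->kco", windows, g))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            contrib = np.einsum("nlo,kco->nlkc", g, w.data)
            np.add.at(gxp, (slice(None), idx), contrib)
            x._accum(gxp[:, pad_lo:pad_lo + L])
    out._backward = back
    return out


def custom(data: np.ndarray, parents: Sequence[Tensor],
           backward: Callable[[np.ndarray], None]) -> Tensor:
    """Wrap a hand-computed forward value with a hand-written backward."""
    return Tensor(data, parents=tuple(parents), backward=backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction; operates on a list of Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
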