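"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the permeability nets need: broadcasted
arithmetic, (batched) matrix products, reductions, softmax, layer
normalization, ReLU, concatenation and 1D convolution with either zero or
circular padding.  Gradients are accumulated by topological traversal of the
recorded graph.  The array dtype is float32 by default (set_dtype switches
to float64, e.g. for finite-difference verification); given fixed seeds the
computation is bit-reproducible either way.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "conv1d", "layer_norm", "relu",
           "softmax", "set_dtype", "get_dtype"]

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global array dtype (float32 default; float64 for checks)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum the extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _init_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(g * self.data, other.shape)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** (-1.0)
        return self * (1.0 / other)

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += g * p * self.data ** (p - 1)

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(
                    g @ np.swapaxes(other.data, -1, -2), self.shape
                )
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(
                    np.swapaxes(self.data, -1, -2) @ g, other.shape
                )

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += g.reshape(old)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._init_grad()
                self.grad += g.transpose(*inv)

        return self._make(self.data.transpose(*axes), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            self._init_grad()
            if axis is None:
                self.grad += g
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver -----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._init_grad()
        self.grad += np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


# -- nonlinearities and structured ops ---------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)

    def backward(g):
        if x.requires_grad:
            x._init_grad()
            x.grad += g * mask

    return x._make(x.data * mask, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._init_grad()
            dot = (g * s).sum(axis=axis, keepdims=True)
            x.grad += s * (g - dot)

    return x._make(s, (x,), backward)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis to zero mean / unit variance."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    d = x.data.shape[-1]

    def backward(g):
        if x.requires_grad:
            x._init_grad()
            gm = g.mean(axis=-1, keepdims=True)
            gy = (g * y).mean(axis=-1, keepdims=True)
            x.grad += inv * (g - gm - y * gy)
        _ = d

    return x._make(y, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._init_grad()
                t.grad += piece

    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _window_indices(L: int, k: int, circular: bool) -> tuple[np.ndarray, np.ndarray]:
    """Index/validity arrays for length-k windows centred at each position."""
    half = k // 2
    offsets = np.arange(-half, half + 1)
    idx = np.arange(L)[:, None] + offsets[None, :]
    if circular:
        return idx % L, np.ones((L, k), dtype=bool)
    valid = (idx >= 0) & (idx < L)
    return np.clip(idx, 0, L - 1), valid


def conv1d(x: Tensor, w: Tensor, b: Tensor, circular: bool = False) -> Tensor:
    """1D convolution over the sequence axis.

    x: (B, L, C_in); w: (k, C_in, C_out); b: (C_out,).  'Same' output length;
    zero padding by default, wrap-around padding when ``circular`` (the
    closed-loop treatment of a cyclic sequence).
    """
    B, L, Cin = x.data.shape
    k, Cin2, Cout = w.data.shape
    if Cin != Cin2:
        raise ValueError("channel mismatch in conv1d")
    idx, valid = _window_indices(L, k, circular)
    win = x.data[:, idx, :] * valid[None, :, :, None]  # (B, L, k, Cin)
    cols = win.reshape(B, L, k * Cin)
    wmat = w.data.reshape(k * Cin, Cout)
    out_data = cols @ wmat + b.data

    def backward(g):
        if b.requires_grad:
            b._init_grad()
            b.grad += g.sum(axis=(0, 1))
        if w.requires_grad:
            w._init_grad()
            w.grad += (cols.reshape(-1, k * Cin).T @ g.reshape(-1, Cout)).reshape(
                k, Cin, Cout
            )
        if x.requires_grad:
            x._init_grad()
            gcols = (g @ wmat.T).reshape(B, L, k, Cin) * valid[None, :, :, None]
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), idx), gcols)
            x.grad += gx

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in (x, w, b))
    if out.requires_grad:
        out._prev = (x, w, b)
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
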