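"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the staging network needs: broadcasting
arithmetic, (batched) matmul, the LSTM/attention nonlinearities, softmax,
1-D convolution, slicing/concat/stack and reductions. Gradients are dense
float64 arrays; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-self.data, self.requires_grad, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        out = np.matmul(self.data, other.data)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor(out, self.requires_grad or other.requires_grad, (self, other), bwd)

    # -- nonlinearities ------------------------------------------------------
    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self, y=y):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return Tensor(y, self.requires_grad, (self,), bwd)

    def tanh(self):
        y = np.tanh(self.data)

        def bwd(g, a=self, y=y):
            if a.requires_grad:
                a._accum(g * (1.0 - y * y))

        return Tensor(y, self.requires_grad, (self,), bwd)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        y = np.where(mask, self.data, slope * self.data)

        def bwd(g, a=self, mask=mask, slope=slope):
            if a.requires_grad:
                a._accum(g * np.where(mask, 1.0, slope))

        return Tensor(y, self.requires_grad, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor(np.log(self.data), self.requires_grad, (self,), bwd)

    def exp(self):
        y = np.exp(self.data)

        def bwd(g, a=self, y=y):
            if a.requires_grad:
                a._accum(g * y)

        return Tensor(y, self.requires_grad, (self,), bwd)

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient is passed through only where unclipped."""
        y = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi

        def bwd(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor(y, self.requires_grad, (self,), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, y=y, axis=axis):
            if a.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))

        return Tensor(y, self.requires_grad, (self,), bwd)

    # -- reductions & shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      self.requires_grad, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor(self.data.reshape(*shape), self.requires_grad, (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g, a=self, inv=inv):
            if a.requires_grad:
                a._accum(g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), self.requires_grad, (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor(self.data[idx], self.requires_grad, (self,), bwd)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # free intermediate grads/graph
                node.grad = None if node._backward is not None else node.grad
                node._parents = ()
                node._backward = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  any(t.requires_grad for t in tensors), tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g, ts=tensors, axis=axis):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  any(t.requires_grad for t in tensors), tuple(tensors), bwd)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, padding: int) -> Tensor:
    """1-D convolution, stride 1.

    x: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,).
    Output length = L + 2*padding - K + 1.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    B, C, L = x.data.shape
    O, C2, K = weight.data.shape
    if C != C2:
        raise ValueError(f"conv1d channel mismatch: input has {C}, weight expects {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B, C, Lout, K)
    y = np.einsum("bclk,ock->bol", win, weight.data, optimize=True) + bias.data[:, None]
    Lout = y.shape[2]

    def bwd(g, x=x, weight=weight, bias=bias, win=win, padding=padding, L=L, K=K, Lout=Lout):
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            weight._accum(np.einsum("bol,bclk->ock", g, win, optimize=True))
        if x.requires_grad:
            dxp = np.zeros((g.shape[0], weight.data.shape[1], L + 2 * padding))
            for k in range(K):
                dxp[:, :, k:k + Lout] += np.einsum("bol,oc->bcl", g, weight.data[:, :, k],
                                                   optimize=True)
            x._accum(dxp[:, :, padding:padding + L] if padding else dxp)

    return Tensor(y, x.requires_grad or weight.requires_grad or bias.requires_grad,
                  (x, weight, bias), bwd)
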