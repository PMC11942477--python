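"""A compact reverse-mode automatic-differentiation engine over numpy.

Just enough tape-based autodiff to express transformer encoders, windowed
attention, fusion blocks and the U-Net style decoder: broadcast-aware
arithmetic, batched matmul, shape ops, gathers, softmax/layer-norm
building blocks and the activations used by the models. Gradients are
accumulated by a topological backward sweep from a scalar loss.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
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
    """An n-d array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: Optional[np.ndarray] = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        # Copy-on-write accumulation: the first contribution is stored by
        # reference (backward fns never mutate what they pass), later ones
        # allocate a fresh sum so aliased gradients stay uncorrupted.
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backward sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _coerce(self, other) -> "Tensor":
        """Wrap non-Tensor operands; scalars adopt this tensor's float dtype."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0 and arr.dtype.kind == "f" and self.data.dtype.kind == "f":
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bwd(g):
            self._accum(g.transpose(inv))

        out._backward = bwd
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    def roll(self, shift, axis):
        out = Tensor(np.roll(self.data, shift, axis=axis), parents=(self,))
        neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift

        def bwd(g):
            self._accum(np.roll(g, neg, axis=axis))

        out._backward = bwd
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            self._accum(g * val)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            self._accum(g / self.data)

        out._backward = bwd
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            self._accum(g * 0.5 / val)

        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            self._accum(g * mask)

        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            self._accum(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, parents=(self,))

        def bwd(g):
            self._accum(g * val * (1.0 - val))

        out._backward = bwd
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            self._accum(g * (1.0 - val * val))

        out._backward = bwd
        return out

    def selu(self):
        pos = self.data > 0
        expm = np.exp(np.minimum(self.data, 0.0)) - 1.0
        val = _SELU_SCALE * np.where(pos, self.data, _SELU_ALPHA * expm)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            dd = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * (expm + 1.0))
            self._accum(g * dd)

        out._backward = bwd
        return out

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Fused layer normalization over the last axis with affine params."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data,
                     parents=(self, gamma, beta))
        D = self.data.shape[-1]

        def bwd(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).reshape(-1, D).sum(axis=0))
            if beta.requires_grad:
                beta._accum(g.reshape(-1, D).sum(axis=0))
            if self.requires_grad:
                gh = g * gamma.data
                term = (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
                self._accum(term * inv)

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, parents=(self,))

        def bwd(g):
            dot = (g * val).sum(axis=axis, keepdims=True)
            self._accum(val * (g - dot))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def bwd(g):
        for n, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, n, axis=axis))

    out._backward = bwd
    return out


def gather_rows(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: rows of ``weight`` selected by integer ``idx``."""
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], parents=(weight,))

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx.reshape(-1),
                  g.reshape(-1, weight.data.shape[-1]))
        weight._accum(full)

    out._backward = bwd
    return out


def mean_pool(x: Tensor, axis: int) -> Tensor:
    return x.mean(axis=axis)
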