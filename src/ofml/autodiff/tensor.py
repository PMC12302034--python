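"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a double-precision ``ndarray`` together with an optional
gradient and a closure that propagates incoming gradients to its parents.
Calling :meth:`Tensor.backward` on a scalar runs the tape in reverse
topological order.  The op set is exactly what the dual-branch classifier
needs: broadcasted arithmetic, batched matmul, reductions, reshaping/slicing,
concatenation, elementwise nonlinearities and a numerically stable
log-softmax.  Convolution and pooling primitives live in
:mod:`ofml.autodiff.functional`.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

DEFAULT_DTYPE = np.float64


def _as_array(value, dtype=DEFAULT_DTYPE) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast relative to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "retains_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data) if not isinstance(data, np.ndarray) else data.astype(DEFAULT_DTYPE, copy=False)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.retains_grad = False

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def retain_grad(self) -> "Tensor":
        self.retains_grad = True
        return self

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without an argument needs a scalar tensor")
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)

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
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None or node.retains_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(g, other.shape)))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / other.data

        def backward(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            )

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, exponent: float):
        data = self.data**exponent

        def backward(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return Tensor._make(data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else g * b
            else:
                gb_T = np.swapaxes(b, -1, -2) if b.ndim > 1 else b[None, :]
                ga = g @ gb_T if b.ndim > 1 else np.expand_dims(g, -1) * b[None, :]
            if b.ndim == 1:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else a * g
                gb = gb.reshape(-1, *b.shape).sum(axis=0) if gb.shape != b.shape else gb
            else:
                ga_T = np.swapaxes(a, -1, -2)
                gb = ga_T @ g
            return (
                (self, _unbroadcast(ga, self.shape)),
                (other, _unbroadcast(gb, other.shape)),
            )

        return Tensor._make(data, (self, other), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.shape).astype(DEFAULT_DTYPE)),)

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def var(self, axis=None, keepdims: bool = False):
        mu = self.mean(axis=axis, keepdims=True)
        centered = self - mu
        out = (centered * centered).mean(axis=axis, keepdims=keepdims)
        return out

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)
        old_shape = self.shape

        def backward(g):
            return ((self, g.reshape(old_shape)),)

        return Tensor._make(data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        data = self.data.transpose(axes)
        inverse = np.argsort(axes)

        def backward(g):
            return ((self, g.transpose(inverse)),)

        return Tensor._make(data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor._make(data, (self,), backward)

    # ---------------------------------------------------------- element-wise
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            return ((self, g * data),)

        return Tensor._make(data, (self,), backward)

    def log(self):
        data = np.log(self.data)

        def backward(g):
            return ((self, g / self.data),)

        return Tensor._make(data, (self,), backward)

    def sqrt(self):
        data = np.sqrt(self.data)

        def backward(g):
            return ((self, g * 0.5 / data),)

        return Tensor._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = self.data * mask

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(data, (self,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit: x * Phi(x)."""
        x = self.data.astype(np.float64)
        phi = 0.5 * (1.0 + _special.erf(x / np.sqrt(2.0)))
        data = (x * phi).astype(DEFAULT_DTYPE)
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        local = (phi + x * pdf).astype(DEFAULT_DTYPE)

        def backward(g):
            return ((self, g * local),)

        return Tensor._make(data, (self,), backward)

    def clip_min(self, floor: float):
        mask = self.data > floor
        data = np.maximum(self.data, floor)

        def backward(g):
            return ((self, g * mask),)

        return Tensor._make(data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        data = shifted - logsumexp
        softmax = np.exp(data)

        def backward(g):
            return ((self, g - softmax * g.sum(axis=axis, keepdims=True)),)

        return Tensor._make(data, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple((t, piece) for t, piece in zip(tensors, pieces))

    return Tensor._make(data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = [t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) for t in tensors]
    return concat(expanded, axis=axis)
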