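"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations needed by the model zoo are implemented: broadcasting
arithmetic, (batched) matmul, reshapes/transposes, reductions, the usual
pointwise nonlinearities, softmax, concatenation, basic slicing and
constant padding.  Gradients flow through a dynamically recorded tape;
``Tensor.backward()`` runs a topological sweep.

The engine is deliberately small and CPU-only; correctness is enforced by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "no_grad", "set_default_dtype"]

#: Working precision of the engine.  Single precision is the customary
#: choice for training networks of this size; tests that compare against
#: finite differences switch to float64.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor method
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data + other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor._from_op(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(
                    -g * self.data / (other.data**2), other.data.shape
                ),
            ),
        )

    def __pow__(self, p: float):
        return Tensor._from_op(
            self.data**p,
            (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (
                _unbroadcast(ga, a.shape),
                _unbroadcast(gb, b.shape),
            )

        return Tensor._from_op(a @ b, (self, other), backward)

    # -- shape ---------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def swapaxes(self, a: int, b: int):
        return Tensor._from_op(
            np.swapaxes(self.data, a, b),
            (self,),
            lambda g: (np.swapaxes(g, a, b),),
        )

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            full[key] = g
            return (full,)

        return Tensor._from_op(self.data[key], (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the two middle axes of a (B, H, W, C) tensor."""
        widths = ((0, 0), (pad, pad), (pad, pad), (0, 0))
        return Tensor._from_op(
            np.pad(self.data, widths),
            (self,),
            lambda g: (g[:, pad:-pad, pad:-pad, :],),
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = (
            self.data.size
            if axis is None
            else np.prod(
                [self.data.shape[a] for a in np.atleast_1d(axis)]
            )
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(
            self.data * mask, (self,), lambda g: (g * mask,)
        )

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(y, (self,), lambda g: (g * y * (1.0 - y),))

    def tanh(self):
        y = np.tanh(self.data)
        return Tensor._from_op(y, (self,), lambda g: (g * (1.0 - y * y),))

    def log(self):
        return Tensor._from_op(
            np.log(self.data), (self,), lambda g: (g / self.data,)
        )

    def exp(self):
        y = np.exp(self.data)
        return Tensor._from_op(y, (self,), lambda g: (g * y,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed only where unclamped."""
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._from_op(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return Tensor._from_op(y, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate(datas, axis=axis), tuple(tensors), backward
    )
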