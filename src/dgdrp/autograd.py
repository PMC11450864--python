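"""A compact reverse-mode automatic differentiation engine on numpy arrays.

The model here is small (mechanism graphs of tens of nodes, gene universes
of a few thousand), so a vectorized tape-based engine over dense numpy
arrays is entirely adequate and keeps the whole training stack dependency-
free. Every operation records its inputs and a closure computing the local
vector-Jacobian product; ``Tensor.backward()`` runs the tape in reverse
topological order.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape. ``matmul`` supports batched operands
(stacks of matrices) the same way ``numpy.matmul`` does, with both operands
at least 2-D.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

#: Element dtype for all tensors. float64 by default (exact gradient checks);
#: training harnesses may switch to float32 for speed via `default_dtype`.
DTYPE = np.float64


@contextmanager
def default_dtype(dtype):
    """Temporarily set the element dtype for newly created tensors."""
    global DTYPE
    previous = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def astensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()
        self._grad_shared = False

    # -- construction of derived tensors ------------------------------------
    @staticmethod
    def _from_op(data, prev, backward, requires_grad=None):
        out = Tensor(data)
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in prev)
        out.requires_grad = requires_grad
        if requires_grad:
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # Copy-on-write: the first contribution aliases the incoming buffer
        # (which may be shared with other tensors); a second contribution
        # allocates. No in-place update ever touches a shared buffer.
        if self.grad is None:
            self.grad = grad
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        a, b = self, astensor(other)
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, astensor(other)
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, astensor(other)
        out_data = a.data / b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data ** 2, b.data.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._from_op(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, astensor(other)
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul operands must be at least 2-D")
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2),
                                           a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g,
                                           b.data.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._from_op(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1 - out_data ** 2))

        return Tensor._from_op(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * out_data * (1 - out_data))

        return Tensor._from_op(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        a = self
        mask = a.data > 0
        slope = np.where(mask, 1.0, negative_slope)

        def backward(g):
            a._accumulate(g * slope)

        return Tensor._from_op(a.data * slope, (a,), backward)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        out_data = np.where(a.data > 0, a.data, neg)

        def backward(g):
            a._accumulate(g * np.where(a.data > 0, 1.0, neg + alpha))

        return Tensor._from_op(out_data, (a,), backward)

    # -- reductions / shaping --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._from_op(a.data.reshape(shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._from_op(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, key, g)
            a._accumulate(grad)

        return Tensor._from_op(a.data[key], (a,), backward)

    # -- autodiff driver -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, iter(self._prev))]
        visited.add(id(self))
        while stack:
            node, children = stack[-1]
            advanced = False
            for child in children:
                if id(child) not in visited:
                    visited.add(id(child))
                    stack.append((child, iter(child._prev)))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                topo.append(node)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, stop)
                t._accumulate(g[tuple(idx)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax along `axis` restricted to positions where `mask` is True.

    Masked-out positions get probability 0. Rows must have at least one
    unmasked entry.
    """
    a = astensor(x)
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), a.data.shape)
    if not mask.any(axis=axis).all():
        raise ValueError("masked_softmax: a row has no unmasked entry")
    neg = np.where(mask, a.data, -np.inf)
    shifted = neg - neg.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        # d softmax: s * (g - sum(g * s))
        inner = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - inner))

    return Tensor._from_op(out_data, (a,), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Batched row gather: x (B, n, d), idx (B, k) -> (B, k, d)."""
    a = astensor(x)
    idx = np.asarray(idx)
    expanded = idx[..., None]
    out_data = np.take_along_axis(a.data, np.broadcast_to(
        expanded, idx.shape + (a.data.shape[-1],)), axis=-2)

    def backward(g):
        grad = np.zeros_like(a.data)
        b = np.arange(idx.shape[0])[:, None, None]
        np.add.at(grad, (b, expanded, np.arange(a.data.shape[-1])[None, None, :]), g)
        a._accumulate(grad)

    return Tensor._from_op(out_data, (a,), backward)


def stack_params(values, requires_grad=True) -> Tensor:
    return Tensor(np.asarray(values, dtype=float), requires_grad=requires_grad)
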