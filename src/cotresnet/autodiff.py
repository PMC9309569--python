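"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is define-by-run: every operation on a :class:`Tensor` records its
parents and a backward closure, and :meth:`Tensor.backward` walks the graph in
reverse topological order accumulating gradients.  Only the operations needed
by convolutional residual networks are provided (broadcast arithmetic, matmul,
reductions, reshapes, neighborhood unfolding); everything higher-level —
convolution, pooling, normalization, attention — is composed from these in
:mod:`cotresnet.nn` and :mod:`cotresnet.blocks`, so a finite-difference check
of the primitives validates the whole stack.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "unfold_nbhd",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        else:
            out._parents = ()
            out._backward = None
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deeper than Python's recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._op(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._op(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._op(data, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            self._accum(g * data)

        return Tensor._op(data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        data = np.where(mask, self.data, 0)

        def backward(g):
            self._accum(g * mask)

        return Tensor._op(data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        data = np.matmul(self.data, other.data)

        def backward(g):
            self._accum(
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.data.shape)
            )
            other._accum(
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.data.shape)
            )

        return Tensor._op(data, (self, other), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._op(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            expanded = data if keepdims else np.expand_dims(data, axis)
            mask = self.data == expanded
            # split gradient among ties so the op stays exactly differentiable
            counts = mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * (gg / counts))

        return Tensor._op(data, (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, shape):
        old = self.data.shape
        data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._op(data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._op(data, (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._op(data, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def concat(tensors, axis: int) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._op(data, tuple(tensors), backward)


def unfold_nbhd(
    x: Tensor, kernel: int, stride: int = 1, padding: int = 0, pad_value: float = 0.0
) -> Tensor:
    """Extract every kernel×kernel neighborhood of a (N, C, H, W) map.

    Returns a (N, C, kernel², H_out, W_out) tensor: position (h, w) of the
    output holds the flattened neighborhood centred on the corresponding input
    window.  This is the im2col primitive behind convolution, pooling and the
    local attention aggregation.
    """
    n, c, h, w = x.data.shape
    k, s, p = kernel, stride, padding
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(f"kernel {k} with stride {s}, padding {p} does not fit input {h}x{w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=pad_value)
    cols = np.empty((n, c, k * k, ho, wo), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]

    def backward(g):
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += g[:, :, i * k + j]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        x._accum(dxp)

    return Tensor._op(cols, (x,), backward)


def softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
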