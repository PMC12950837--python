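"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole detector runs at desk scale (feature grids of a few thousand
positions), so a small dynamic tape in float64 is both fast enough and
numerically comfortable for the flow's invertibility and log-det checks.
Only the operations the model needs are implemented.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray

_DTYPE = np.float64


def _unbroadcast(grad: Array, shape: Tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional backward closure on a dynamic tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[Array], None]] = None,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = requires_grad
        self.grad: Optional[Array] = None
        self._parents = _parents
        self._backward = _backward

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def numpy(self) -> Array:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # ---- autodiff machinery --------------------------------------------
    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[Array] = None) -> None:
        """Reverse-sweep the tape from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can be deep (8 blocks x 4 scales)
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # ---- elementwise nonlinearities ------------------------------------
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * (1.0 - val**2))

        out._backward = bw
        return out

    def atan(self) -> "Tensor":
        out = Tensor(np.arctan(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / (1.0 + self.data**2))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    # ---- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: Array) -> None:
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    # ---- slicing along the channel axis (axis=1) ------------------------
    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)
        out = Tensor(self.data[sl], requires_grad=self.requires_grad, _parents=(self,))

        def bw(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[sl] = g
                self._accumulate(full)

        out._backward = bw
        return out

    def take(self, indices: Sequence[int], axis: int = 1) -> "Tensor":
        idx = np.asarray(indices)
        out = Tensor(
            np.take(self.data, idx, axis=axis),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def bw(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(np.moveaxis(full, axis, 0), idx, np.moveaxis(g, axis, 0))
                self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        _parents=tuple(ts),
    )
    sizes = [t.shape[axis] for t in ts]

    def bw(g: Array) -> None:
        start = 0
        for t, sz in zip(ts, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + sz)
                t._accumulate(g[tuple(sl)])
            start += sz

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        _parents=tuple(ts),
    )

    def bw(g: Array) -> None:
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bw
    return out
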