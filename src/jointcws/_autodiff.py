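"""Compact reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` and records the
operations that produced it; calling :meth:`Tensor.backward` on a scalar
result accumulates ``grad`` arrays on every upstream tensor that has
``requires_grad`` set.  The op set is exactly what the joint
segmentation/classification model needs: broadcast arithmetic, matmul
(including batched 3-D @ 2-D), the sigmoid/tanh/relu nonlinearities,
axis reductions, slicing/stacking along the time axis, embedding lookup,
and fused masked softmax cross-entropy losses.

All computation is float64 and single-threaded numpy, so identical seeds
give bit-identical results on a fixed platform.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack_time", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "grad_mask", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GradMode.enabled
        self.grad: np.ndarray | None = None
        self.grad_mask: np.ndarray | None = None  # rows frozen by the optimizer
        self._parents: tuple[Tensor, ...] = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GradMode.enabled and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(parents), _backward=backward)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = np.matmul(a, b)

        def backward(g):
            if a.ndim == b.ndim == 2:
                return (g @ b.T, a.T @ g)
            if a.ndim == 3 and b.ndim == 2:
                ga = np.matmul(g, b.T)
                gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                return (ga, gb)
            raise NotImplementedError(f"matmul backward for {a.shape} @ {b.shape}")

        return self._result(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._result(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data * out_data),)

        return self._result(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            return (g * (self.data > 0.0),)

        return self._result(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._result(np.log(self.data), (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return self._result(self.data.reshape(*shape), (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice ``[start, start+length)`` along ``axis``."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return self._result(self.data[idx], (self,), backward)

    def at_time(self, t: int):
        """Select time step ``t`` of a (batch, time, dim) tensor -> (batch, dim)."""

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, t, :] = g
            return (full,)

        return self._result(self.data[:, t, :], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            return (np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy(),)

        return self._result(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def max(self, axis: int):
        out_data = self.data.max(axis=axis)
        arg = self.data.argmax(axis=axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis
            )
            return (full,)

        return self._result(out_data, (self,), backward)

    # -- embedding lookup -----------------------------------------------------
    def take_rows(self, indices: np.ndarray):
        """Gather rows of a (vocab, dim) matrix: result shape indices.shape + (dim,)."""
        indices = np.asarray(indices)

        def backward(g):
            gw = np.zeros_like(self.data)
            np.add.at(gw, indices.reshape(-1), g.reshape(-1, g.shape[-1]))
            return (gw,)

        return self._result(self.data[indices], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        # fresh grads on every call: several losses may share one graph
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for i in range(len(tensors)):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(g[tuple(idx)])
        return tuple(grads)

    return Tensor._result(out_data, tensors, backward)


def stack_time(tensors: Sequence[Tensor]) -> Tensor:
    """Stack (batch, dim) tensors into (batch, time, dim)."""
    out_data = np.stack([t.data for t in tensors], axis=1)

    def backward(g):
        return tuple(g[:, t, :] for t in range(len(tensors)))

    return Tensor._result(out_data, tuple(tensors), backward)
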