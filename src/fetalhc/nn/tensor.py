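"""A compact reverse-mode autodiff engine on numpy arrays.

Only what the detector-regressor needs: tensors carry a float32 payload and
an optional backward graph of ``(parent, grad_fn)`` edges. Gradients are
propagated in reverse topological order; subgraphs whose leaves do not
require gradients are pruned at construction time, so frozen training
stages skip their backward work entirely.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        if isinstance(data, np.ndarray):
            self.data = data if data.dtype == np.float32 else data.astype(np.float32)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
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
            for parent, _ in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            g = node.grad
            if g is None or not node._parents:
                continue
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib
            if node is not self:
                node.grad = None  # free intermediate gradients

    def zero_grad(self):
        self.grad = None


def make(data: np.ndarray, parents) -> Tensor:
    """Build a graph node; drops the graph under ``no_grad`` or constant input."""
    if grad_enabled():
        parents = tuple((p, fn) for p, fn in parents if p.requires_grad)
        if parents:
            return Tensor(data, requires_grad=True, parents=parents)
    return Tensor(data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
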