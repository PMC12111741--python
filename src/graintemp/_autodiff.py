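"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to train the forecasting networks: broadcast-aware
elementwise arithmetic, matrix products, the saturating nonlinearities,
a valid 1-D cross-correlation, non-overlapping max pooling, reductions and
basic indexing.  Gradients are accumulated on a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "maxpool1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` back down to `shape` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; LSTM graphs get deep
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self.grad += -g
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._coerce(other)
        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g
        return Tensor._make(self.data @ other.data, (self, other), backward)

    def square(self):
        def backward(g):
            if self.requires_grad:
                self.grad += 2.0 * self.data * g
        return Tensor._make(self.data**2, (self,), backward)

    # -- nonlinearities -----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        def backward(g):
            if self.requires_grad:
                self.grad += (1.0 - y**2) * g
        return Tensor._make(y, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            if self.requires_grad:
                self.grad += y * (1.0 - y) * g
        return Tensor._make(y, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            if self.requires_grad:
                self.grad += mask * g
        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions and shaping ----------------------------------------------

    def sum(self):
        def backward(g):
            if self.requires_grad:
                self.grad += np.broadcast_to(g, self.data.shape)
        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        y = self.data.mean(axis=axis)
        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self.grad += np.broadcast_to(g, self.data.shape) / n
                else:
                    self.grad += np.expand_dims(g, axis) / n
        return Tensor._make(y, (self,), backward)

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)
        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                self.grad[idx] += g
        return Tensor._make(self.data[idx], (self,), backward)


# ---------------------------------------------------------------------------
# Structured ops
# ---------------------------------------------------------------------------


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid 1-D cross-correlation.

    x: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,).
    Output: (B, C_out, L - K + 1).
    """
    B, C_in, L = x.data.shape
    C_out, _, K = weight.data.shape
    if L < K:
        raise ValueError(f"input length {L} shorter than kernel {K}")
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)  # (B,Cin,Lout,K)
    out = np.einsum("bclk,ock->bol", cols, weight.data) + bias.data[None, :, None]
    L_out = L - K + 1

    def backward(g):  # g: (B, C_out, L_out)
        if weight.requires_grad:
            weight.grad += np.einsum("bclk,bol->ock", cols, g)
        if bias.requires_grad:
            bias.grad += g.sum(axis=(0, 2))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, :, k : k + L_out] += np.einsum("bol,oc->bcl", g, weight.data[:, :, k])
            x.grad += gx

    return Tensor._make(out, (x, weight, bias), backward)


def maxpool1d(x: Tensor, pool_size: int) -> Tensor:
    """Non-overlapping max pooling over the last axis; remainder truncated."""
    B, C, L = x.data.shape
    if L < pool_size:
        raise ValueError(f"input length {L} shorter than pool size {pool_size}")
    L_out = L // pool_size
    trimmed = x.data[:, :, : L_out * pool_size].reshape(B, C, L_out, pool_size)
    arg = trimmed.argmax(axis=3)
    out = np.take_along_axis(trimmed, arg[..., None], axis=3)[..., 0]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros((B, C, L_out, pool_size))
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
            x.grad[:, :, : L_out * pool_size] += gx.reshape(B, C, L_out * pool_size)

    return Tensor._make(out, (x,), backward)
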