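"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine providing exactly the operations the staging
network needs: broadcasting arithmetic, matmul, the usual activations,
1-D convolution and max-pooling primitives, layer normalisation and
log-softmax.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`, which walks the recorded graph in reverse
topological order.

The engine is deliberately eager and single-threaded: given identical
inputs and parameters it produces bitwise-identical forward values and
gradients, which the training pipeline relies on for its reproducibility
guarantee.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return  # untracked leaf (e.g. input data): no gradient needed
        if self.grad is None:
            # first contribution: take a writable copy instead of
            # zero-filling then adding (saves a full pass)
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    @staticmethod
    def _lift(other, dtype) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=dtype))

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; recursion depth would scale with sequence length
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @classmethod
    def _make(cls, data: np.ndarray, parents: tuple["Tensor", ...], backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            # requires_grad propagates so downstream ops keep recording
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data + other.data

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other, self.dtype))

    def __rsub__(self, other):
        return self._lift(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data * other.data

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data / other.data

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor._make(out_data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data @ other.data

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # -- activations ------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def tanh(self):
        y = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - y * y))

        return Tensor._make(y, (self,), bwd)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * y * (1.0 - y))

        return Tensor._make(y, (self,), bwd)

    def exp(self):
        y = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * y)

        return Tensor._make(y, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    # -- reductions / reshaping ------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), bwd)

    # -- fused / structured ops ------------------------------------------

    def log_softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        y = x - m - np.log(np.exp(x - m).sum(axis=axis, keepdims=True))

        def bwd(g):
            self._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        return Tensor._make(y, (self,), bwd)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then apply the learnable affine."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = xhat * gamma.data + beta.data

        def bwd(g):
            reduce_axes = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=reduce_axes))
            beta._accumulate(g.sum(axis=reduce_axes))
            gh = g * gamma.data
            gx = inv * (
                gh
                - gh.mean(axis=-1, keepdims=True)
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            )
            self._accumulate(gx)

        return Tensor._make(out_data, (self, gamma, beta), bwd)

    def conv1d(self, weight: "Tensor", bias: "Tensor", stride: int = 1):
        """Valid-mode strided 1-D convolution (cross-correlation).

        Input is (B, C, L), weight (F, C, K), bias (F,); output (B, F, T)
        with T = floor((L - K) / stride) + 1.
        """
        B, C, L = self.shape
        F, Cw, K = weight.shape
        if Cw != C:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        if L < K:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        T = (L - K) // stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(self.data, K, axis=2)
        windows = windows[:, :, ::stride, :]  # (B, C, T, K)
        cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
            B * T, C * K
        )
        wmat = weight.data.reshape(F, C * K)
        out = cols @ wmat.T + bias.data
        out_data = out.reshape(B, T, F).transpose(0, 2, 1)

        def bwd(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * T, F)
            weight._accumulate((g2.T @ cols).reshape(F, C, K))
            bias._accumulate(g2.sum(axis=0))
            if not self.requires_grad:
                return  # raw-input layer: no input gradient needed
            gcols = (g2 @ wmat).reshape(B, T, C, K).transpose(0, 2, 1, 3)
            gx = np.zeros_like(self.data)
            for k in range(K):
                gx[:, :, k : k + stride * T : stride] += gcols[:, :, :, k]
            self._accumulate(gx)

        return Tensor._make(out_data, (self, weight, bias), bwd)

    def max_pool1d(self, size: int):
        """Non-overlapping temporal max pool; a trailing partial window is dropped."""
        B, C, L = self.shape
        T = L // size
        trimmed = self.data[:, :, : T * size].reshape(B, C, T, size)
        out_data = trimmed.max(axis=3)

        def bwd(g):
            # route gradient to window maxima by equality mask; exact ties
            # (measure zero for continuous activations) share the gradient
            gx = np.zeros_like(self.data)
            mask = trimmed == out_data[..., None]
            gx[:, :, : T * size] = (mask * g[..., None]).reshape(B, C, T * size)
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), bwd)

    def adaptive_max_pool1d(self, t_out: int):
        """Max-pool to exactly ``t_out`` steps using contiguous variable windows."""
        B, C, L = self.shape
        if t_out > L:
            raise ValueError(f"cannot pool length {L} up to {t_out}")
        bounds = [(i * L) // t_out for i in range(t_out + 1)]
        out_data = np.empty((B, C, t_out), dtype=self.data.dtype)
        argmaxes = []
        for i in range(t_out):
            s, e = bounds[i], bounds[i + 1]
            seg = self.data[:, :, s:e]
            am = seg.argmax(axis=2)
            argmaxes.append(s + am)
            out_data[:, :, i] = np.take_along_axis(seg, am[..., None], axis=2)[..., 0]

        def bwd(g):
            gx = np.zeros_like(self.data)
            bidx, cidx = np.ogrid[:B, :C]
            for i in range(t_out):
                np.add.at(gx, (bidx, cidx, argmaxes[i]), g[:, :, i])
            self._accumulate(gx)

        return Tensor._make(out_data, (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(s, e)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bwd)
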