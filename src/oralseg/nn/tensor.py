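"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine: a :class:`Tensor` wraps a ``float32`` ndarray and
records the operations applied to it; :meth:`Tensor.backward` walks the tape in
reverse topological order and accumulates gradients.  Only the primitives the
segmentation network needs are provided (broadcast arithmetic, matmul, reductions,
shape surgery, 3-D convolution, window gathers, a linear recurrence for
state-space scans).  Gradients are dense; there is no graph retention across
backward calls.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"],
            backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate buffers once consumed
                node._backward = None
                node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        # First set aliases `g` (may be a view); later accumulations are
        # out-of-place, so an aliased buffer is never mutated.
        if g.dtype != np.float32:
            g = g.astype(np.float32)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2),
                                          other.shape))

        return Tensor._op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._op(np.log(self.data), (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        np.divide(1.0, 1.0 + np.exp(-x, where=pos, out=np.zeros_like(x)),
                  out=out_data, where=pos)
        ex = np.exp(x, where=~pos, out=np.zeros_like(x))
        np.divide(ex, 1.0 + ex, out=out_data, where=~pos)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    def silu(self):
        sig = self.sigmoid().data
        out_data = self.data * sig

        def backward(g):
            self._accum(g * (sig * (1.0 + self.data * (1.0 - sig))))

        return Tensor._op(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation (exact enough for training purposes)
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dt = (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * x ** 2)
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._op(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor._op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims=False) -> np.ndarray:
        """Max as a constant (used for numerically stable softmax)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape surgery --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros(self.shape, dtype=np.float32)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._op(out_data, (self,), backward)

    def pad(self, pad_width):
        """Zero padding; `pad_width` as for np.pad."""
        out_data = np.pad(self.data, pad_width)
        slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, self.shape))

        def backward(g):
            self._accum(g[slices])

        return Tensor._op(out_data, (self,), backward)

    def roll(self, shift, axis):
        def backward(g):
            self._accum(np.roll(g, tuple(-s for s in shift), axis))

        return Tensor._op(np.roll(self.data, shift, axis), (self,), backward)

    def take0(self, index: np.ndarray):
        """Gather along axis 0 with an integer index array."""
        out_data = self.data[index]

        def backward(g):
            full = np.zeros(self.shape, dtype=np.float32)
            np.add.at(full, index, g)
            self._accum(full)

        return Tensor._op(out_data, (self,), backward)

    def broadcast_to(self, shape):
        def backward(g):
            self._accum(_unbroadcast(g, self.shape))

        return Tensor._op(np.broadcast_to(self.data, shape).astype(np.float32),
                          (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# composite / fused primitives
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._op(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.max_detached(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.max_detached(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 3-D convolution, stride 1, odd cubic kernel.

    x: (B, Ci, D, H, W); w: (Co, Ci, k, k, k); b: (Co,).
    Implemented as im2col + GEMM; the input gradient is a col2im scatter done
    as k^3 shifted slice-adds.
    """
    B, Ci, D, H, W = x.shape
    Co, Ci2, k, _, _ = w.shape
    assert Ci == Ci2, (Ci, Ci2)
    p = k // 2
    # channels-last internally: one gather into im2col, GEMM, reshape out
    if k == 1:
        cols = np.ascontiguousarray(x.data.transpose(0, 2, 3, 4, 1)
                                    ).reshape(B * D * H * W, Ci)
    else:
        xl = np.empty((B, D + 2 * p, H + 2 * p, W + 2 * p, Ci), dtype=np.float32)
        xl[:] = 0.0
        xl[:, p:p + D, p:p + H, p:p + W, :] = x.data.transpose(0, 2, 3, 4, 1)
        view = np.lib.stride_tricks.sliding_window_view(xl, (k, k, k),
                                                        axis=(1, 2, 3))
        # (B, D, H, W, Ci, k, k, k); the (Ci, k, k, k) trailing order matches
        # the weight layout, so reshape is the single im2col copy
        cols = view.reshape(B * D * H * W, Ci * k ** 3)
    wmat = w.data.reshape(Co, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out_data = np.ascontiguousarray(
        out.reshape(B, D, H, W, Co).transpose(0, 4, 1, 2, 3))

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        go = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)
                                  ).reshape(B * D * H * W, Co)
        if b is not None and b.requires_grad:
            b._accum(go.sum(axis=0))
        if w.requires_grad:
            gw = go.T @ cols
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            if k == 1:
                gcols = go @ wmat  # (BDHW, Ci)
                gx = gcols.reshape(B, D, H, W, Ci).transpose(0, 4, 1, 2, 3)
                x._accum(np.ascontiguousarray(gx))
            else:
                # input gradient = correlation of the output gradient with the
                # spatially flipped kernel: one im2col gather + one GEMM
                gop = np.zeros((B, D + 2 * p, H + 2 * p, W + 2 * p, Co),
                               dtype=np.float32)
                gop[:, p:p + D, p:p + H, p:p + W, :] = \
                    go.reshape(B, D, H, W, Co)
                gview = np.lib.stride_tricks.sliding_window_view(
                    gop, (k, k, k), axis=(1, 2, 3))
                gcols2 = gview.reshape(B * D * H * W, Co * k ** 3)
                wflip = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1, ::-1].transpose(0, 2, 3, 4, 1)
                ).reshape(Co * k ** 3, Ci)
                gx = (gcols2 @ wflip).reshape(B, D, H, W, Ci)
                x._accum(np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3)))

    return Tensor._op(out_data, parents, backward)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour ×factor upsampling of (B, C, D, H, W)."""
    f = factor
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    B, C, D, H, W = x.shape

    def backward(g):
        g = g.reshape(B, C, D, f, H, f, W, f).sum(axis=(3, 5, 7))
        x._accum(g)

    return Tensor._op(out_data, (x,), backward)


def linear_scan(dA: Tensor, dBx: Tensor, Ct: Tensor) -> Tensor:
    """Selective state-space recurrence along axis 1.

    h_t = dA_t * h_{t-1} + dBx_t          (h: (B, C, N), h_{-1} = 0)
    y_t[b, c] = sum_n h_t[b, c, n] * Ct[b, t, n]

    dA, dBx: (B, L, C, N); Ct: (B, L, N); returns y: (B, L, C).
    Backward is the reverse-time adjoint recurrence.
    """
    B, L, C, N = dA.shape
    hs = np.empty((B, L, C, N), dtype=np.float32)
    h = np.zeros((B, C, N), dtype=np.float32)
    a, u, c = dA.data, dBx.data, Ct.data
    for t in range(L):
        h = a[:, t] * h + u[:, t]
        hs[:, t] = h
    y = np.einsum("blcn,bln->blc", hs, c)

    def backward(g):
        gdA = np.zeros_like(a) if dA.requires_grad else None
        gdBx = np.zeros_like(u) if dBx.requires_grad else None
        gCt = np.zeros_like(c) if Ct.requires_grad else None
        gh = np.zeros((B, C, N), dtype=np.float32)
        for t in range(L - 1, -1, -1):
            gh += g[:, t, :, None] * c[:, t, None, :]
            if gCt is not None:
                gCt[:, t] = np.einsum("bc,bcn->bn", g[:, t], hs[:, t])
            if gdBx is not None:
                gdBx[:, t] = gh
            if gdA is not None:
                h_prev = hs[:, t - 1] if t > 0 else 0.0
                gdA[:, t] = gh * h_prev
            gh = gh * a[:, t]
        if gdA is not None:
            dA._accum(gdA)
        if gdBx is not None:
            dBx._accum(gdBx)
        if gCt is not None:
            Ct._accum(gCt)

    return Tensor._op(y, (dA, dBx, Ct), backward)
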