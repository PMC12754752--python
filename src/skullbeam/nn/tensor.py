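"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` walks the tape in reverse topological order accumulating
gradients. The op set is exactly what the LSTM-Conv surrogate needs:
elementwise arithmetic with broadcasting, matmul, the usual activations,
reductions, shape ops, basic-slice indexing, concatenation, 2D convolution
(im2col) and nearest x2 upsampling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_rows", "conv2d", "upsample2",
           "resize_half_vec", "resize_double_vec"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g, other.shape))
        out._backward = bwd
        return out

    # -- activations -------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - out.data ** 2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * s * (1 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * np.sign(self.data))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / np.maximum(out.data, 1e-30))
        return out

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    def swap_last2(self):
        out = Tensor(self.data.swapaxes(-1, -2).copy(), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.swapaxes(-1, -2))
        return out

    def __getitem__(self, idx):
        """Basic (slice/int) indexing only; backward writes into a view."""
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[idx] += g
        out._backward = bwd
        return out


# ---------------------------------------------------------------------------
# free functions


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


def stack_rows(rows: list[Tensor], axis: int) -> Tensor:
    """Stack same-shape tensors along a new axis."""
    out = Tensor(np.stack([r.data for r in rows], axis=axis), _parents=tuple(rows))

    def bwd(g):
        for i, r in enumerate(rows):
            if r.requires_grad:
                r._accum(np.take(g, i, axis=axis))
    out._backward = bwd
    return out


def _im2col(x: np.ndarray, k: int, stride: int, padding: int):
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, ho * wo)
    return cols, ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation); x (B,C,H,W), weight (Cout,Cin,k,k)."""
    b, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    cols, ho, wo = _im2col(x.data, k, stride, padding)
    wmat = weight.data.reshape(cout, cin * k * k)
    out_data = (wmat @ cols).reshape(b, cout, ho, wo) + bias.data.reshape(1, cout, 1, 1)
    out = Tensor(out_data, _parents=(x, weight, bias))

    def bwd(g):
        gmat = g.reshape(b, cout, ho * wo)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("bol,bil->oi", gmat, cols)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("oi,bol->bil", wmat, gmat)
            gcols = gcols.reshape(b, c, k, k, ho, wo)
            gx = np.zeros((b, c, h + 2 * padding, w + 2 * padding))
            for di in range(k):
                for dj in range(k):
                    gx[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride] += gcols[:, :, di, dj]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)
    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of (B,C,H,W)."""
    d = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(d, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            x._accum(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
    out._backward = bwd
    return out


def resize_half_vec(x: Tensor) -> Tensor:
    """Halve the last axis by averaging adjacent pairs (state hand-off)."""
    b, n = x.shape
    out = Tensor(x.data.reshape(b, n // 2, 2).mean(axis=2), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.repeat(g / 2.0, 2, axis=1))
    out._backward = bwd
    return out


def resize_double_vec(x: Tensor) -> Tensor:
    """Double the last axis by repeating entries (state hand-off)."""
    out = Tensor(np.repeat(x.data, 2, axis=1), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            b, n2 = g.shape
            x._accum(g.reshape(b, n2 // 2, 2).sum(axis=2))
    out._backward = bwd
    return out
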