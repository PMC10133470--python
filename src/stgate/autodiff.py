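"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network layers in :mod:`stgate.nn` and :mod:`stgate.model` are built on the
:class:`Tensor` class below.  The design follows the classic tape-less
define-by-run pattern: every operation returns a new ``Tensor`` holding its
parents and a closure that maps the output gradient to per-parent gradients;
``Tensor.backward`` walks the graph in reverse topological order.

Only the operations the model needs are implemented: broadcast arithmetic,
(batched) matrix multiplication, an unpadded 2-D convolution primitive,
reductions, element-wise nonlinearities and a numerically stable softmax.
Everything runs in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv2d", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """N-dimensional array with reverse-mode gradient support."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable parent."""
        if grad is None:
            grad = np.ones_like(self.data)
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
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor(
            self.data**e,
            parents=(self,),
            backward=lambda g: (g * e * self.data ** (e - 1.0),),
        )

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data

        def backward(g):
            ga = _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), self.shape)
            gb = _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), other.shape)
            return ga, gb

        return Tensor(np.matmul(a, b), parents=(self, other), backward=backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            backward=lambda g: (g.reshape(old),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            backward=lambda g: (g.transpose(inv),),
        )

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * out_data,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * (1.0 - out_data**2),))

    def leaky_relu(self, negative_slope: float = 0.2):
        pos = self.data > 0
        factor = np.where(pos, 1.0, negative_slope)
        return Tensor(self.data * factor, parents=(self,), backward=lambda g: (g * factor,))

    def relu(self):
        return self.leaky_relu(0.0)

    def elu(self):
        pos = self.data > 0
        ex = np.exp(np.minimum(self.data, 0.0))
        out_data = np.where(pos, self.data, ex - 1.0)
        factor = np.where(pos, 1.0, ex)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * factor,))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (leaf node registered by :class:`stgate.nn.Module`)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- composite / primitive operations --------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift by a constant max)."""
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Unpadded stride-1 2-D convolution (cross-correlation).

    ``x``: (B, C_in, H, W); ``w``: (C_out, C_in, kh, kw); ``b``: (C_out,).
    Returns (B, C_out, H-kh+1, W-kw+1).  Implemented via im2col + matmul with
    an explicit col2im backward pass.
    """
    xb, wb = x.data, w.data
    batch, cin, height, width = xb.shape
    cout, cin_w, kh, kw = wb.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {cin_w}")
    ho, wo = height - kh + 1, width - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"conv2d: kernel ({kh}x{kw}) larger than input plane ({height}x{width})"
        )
    # (B, C, ho, wo, kh, kw) -> (B*ho*wo, C*kh*kw)
    windows = np.lib.stride_tricks.sliding_window_view(xb, (kh, kw), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(batch * ho * wo, cin * kh * kw)
    wmat = wb.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(batch, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(batch * ho * wo, cout)
        gw = (g2.T @ cols).reshape(wb.shape)
        gcols = (g2 @ wmat).reshape(batch, ho, wo, cin, kh, kw)
        gx = np.zeros_like(xb)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + ho, j : j + wo] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if b is not None:
            return gx, gw, g2.sum(axis=0)
        return gx, gw

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=backward)
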