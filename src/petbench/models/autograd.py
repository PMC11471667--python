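"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the tiny-tier denoisers need: N-dimensional
strided convolution (2D and 3D share one code path built on
``sliding_window_view``), pointwise nonlinearities, arithmetic, and the
reductions used by the loss functions.  Gradients accumulate into ``.grad``
after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(),
                 _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, scalar: float) -> "Tensor":
        if isinstance(scalar, Tensor):
            raise TypeError("only scalar multiplication is supported")
        out = Tensor(self.data * scalar, self.requires_grad, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * scalar)

        out._backward = bw
        return out

    __rmul__ = __mul__

    # -- nonlinearities -----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     self.requires_grad, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------
    def sum_abs(self) -> "Tensor":
        """Sum of absolute values over all elements (L1 norm)."""
        out = Tensor(np.abs(self.data).sum(), self.requires_grad, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        out._backward = bw
        return out

    def mean_abs(self) -> "Tensor":
        return self.sum_abs() * (1.0 / self.data.size)

    def sum_sq(self) -> "Tensor":
        out = Tensor((self.data**2).sum(), self.requires_grad, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * 2.0 * self.data)

        out._backward = bw
        return out

    def mean_sq(self) -> "Tensor":
        return self.sum_sq() * (1.0 / self.data.size)

    def sum_charbonnier(self, eps: float) -> "Tensor":
        root = np.sqrt(self.data**2 + eps**2)
        out = Tensor(root.sum(), self.requires_grad, (self,))

        def bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * self.data / root)

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None,
            stride: int | tuple = 1, padding: int | tuple = 0) -> Tensor:
    """N-dimensional cross-correlation (the deep-learning "convolution").

    ``x``: (N, C_in, *spatial); ``w``: (C_out, C_in, *kernel);
    ``b``: (C_out,) or None.  Works for any spatial rank; the package uses
    rank 2 and 3.
    """
    nd = x.data.ndim - 2
    kernel = w.data.shape[2:]
    stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
    padding = (padding,) * nd if np.isscalar(padding) else tuple(padding)
    if w.data.shape[1] != x.data.shape[1]:
        raise ValueError("channel mismatch between input and kernel")

    pad_width = [(0, 0), (0, 0)] + [(p, p) for p in padding]
    xp = np.pad(x.data, pad_width)
    win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + nd)))
    win = win[(slice(None), slice(None))
              + tuple(slice(None, None, s) for s in stride)]
    # win: (N, C, *out, *kernel) -> cols: (N, prod(out), C*prod(kernel))
    n_batch, c_in = win.shape[:2]
    out_spatial = win.shape[2:2 + nd]
    cols = np.moveaxis(win, 1, 1 + nd)  # (N, *out, C, *kernel)
    cols = np.ascontiguousarray(cols).reshape(
        n_batch, int(np.prod(out_spatial)), c_in * int(np.prod(kernel)))
    w2 = w.data.reshape(w.data.shape[0], -1)
    y = cols @ w2.T  # (N, prod(out), C_out)
    if b is not None:
        y = y + b.data
    y = np.moveaxis(y, -1, 1).reshape(n_batch, w.data.shape[0], *out_spatial)

    requires = x.requires_grad or w.requires_grad or (
        b is not None and b.requires_grad)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, requires, parents)

    def bw() -> None:
        g = out.grad  # (N, C_out, *out)
        g2 = np.moveaxis(g, 1, -1).reshape(n_batch, -1, w.data.shape[0])
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = g2.reshape(-1, w.data.shape[0]).T @ cols.reshape(
                -1, cols.shape[-1])
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = g2 @ w2  # (N, prod(out), C*prod(kernel))
            gcols = gcols.reshape(n_batch, *out_spatial, c_in, *kernel)
            gxp = np.zeros_like(xp)
            for offs in product(*(range(k) for k in kernel)):
                sl = tuple(
                    slice(o, o + s * (osz - 1) + 1, s)
                    for o, s, osz in zip(offs, stride, out_spatial))
                piece = gcols[(slice(None),) + (slice(None),) * nd
                              + (slice(None),) + offs]
                gxp[(slice(None), slice(None)) + sl] += np.moveaxis(
                    piece, -1, 1)
            unpad = tuple(
                slice(p, xp.shape[2 + i] - p) for i, p in enumerate(padding))
            x._accum(gxp[(slice(None), slice(None)) + unpad])

    out._backward = bw
    return out


class Adam:
    """Adam optimizer with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
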