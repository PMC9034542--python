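"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal define-by-run tape: every op returns a new :class:`Tensor`
holding its inputs and a closure that accumulates gradients into them.
Only the operations needed by 2-D convolutional encoder–decoder networks
are provided (convolution, transposed convolution, pooling, batch
normalisation, channel concatenation, pointwise nonlinearities and the
reductions used by the losses).  All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "max_pool2d"]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ graph
    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                if t is not self:
                    t.grad = None  # free intermediate grads eagerly

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad,
                      (self, other), bwd)

    __radd__ = __add__
    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    # ------------------------------------------------------------- pointwise
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def leaky_relu(self, slope=0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data * out_data))

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def log(self):
        out_data = np.log(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)
        out_data = np.abs(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def clip(self, lo, hi):
        """Clamp values; gradient is passed only where not clipped."""
        inside = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * inside)

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    # ------------------------------------------------------------- reductions
    def mean(self):
        out_data = np.float32(self.data.mean())
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape))

        return Tensor(out_data, self.requires_grad, (self,), bwd)

    def sum(self):
        out_data = np.float32(self.data.sum())

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, self.requires_grad, (self,), bwd)


def _unbroadcast(g, shape):
    """Sum gradient g down to the given (broadcast-source) shape."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(np.float32)


def concat(tensors, axis=1):
    """Concatenate along a given axis (channel axis 1 by default)."""
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    req = any(t.requires_grad for t in tensors)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, req, tuple(tensors), bwd)


# ---------------------------------------------------------------- im2col core
def _im2col(x, k, stride, pad):
    """(N,C,H,W) -> (N, C, k, k, OH, OW) patch view copy."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                  j:j + stride * ow:stride]
    return cols, oh, ow


def _col2im(cols, x_shape, k, stride, pad):
    """Adjoint of :func:`_im2col`: scatter-add patches back."""
    n, c, h, w = x_shape
    oh, ow = cols.shape[4], cols.shape[5]
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride,
               j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x, w, b=None, stride=1, padding=0):
    """2-D cross-correlation.  x:(N,Cin,H,W)  w:(Cout,Cin,k,k)  b:(Cout,)."""
    n = x.data.shape[0]
    cout, cin, k, _ = w.data.shape
    cols, oh, ow = _im2col(x.data, k, stride, padding)
    colm = cols.reshape(n, cin * k * k, oh * ow)
    wm = w.data.reshape(cout, cin * k * k)
    out_data = np.matmul(wm, colm).reshape(n, cout, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)
    del cols, colm  # recomputed in bwd: retaining them across the graph is
    # the dominant memory cost of a deep network

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = g.reshape(n, cout, oh * ow)
        if w.requires_grad:
            cols2, _, _ = _im2col(x.data, k, stride, padding)
            colm = cols2.reshape(n, cin * k * k, oh * ow)
            dw = np.matmul(gm, colm.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = np.matmul(wm.T, gm).reshape(n, cin, k, k, oh, ow)
            x._accum(_col2im(dcol, x.data.shape, k, stride, padding))

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(out_data, req, parents, bwd)


def conv_transpose2d(x, w, b=None, stride=2, padding=0, output_padding=0):
    """Transposed convolution.  x:(N,Cin,H,W)  w:(Cin,Cout,k,k).

    Output spatial size is ``(H-1)*stride - 2*padding + k + output_padding``.
    """
    n, cin, h, wd = x.data.shape
    _, cout, k, _ = w.data.shape
    h_full = (h - 1) * stride + k
    w_full = (wd - 1) * stride + k
    h_out = h_full - 2 * padding + output_padding
    w_out = w_full - 2 * padding + output_padding

    xm = x.data.reshape(n, cin, h * wd)
    wm = w.data.reshape(cin, cout * k * k)
    cols = np.matmul(wm.T, xm).reshape(n, cout, k, k, h, wd)
    full = _col2im(cols, (n, cout, h_full, w_full), k, stride, 0)
    out_data = full[:, :, padding:padding + h_out, padding:padding + w_out]
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gfull = np.zeros((n, cout, h_full, w_full), dtype=np.float32)
        gfull[:, :, padding:padding + h_out, padding:padding + w_out] = g
        gcols, _, _ = _im2col(gfull, k, stride, 0)  # (N,Cout,k,k,H,W)
        gcolm = gcols.reshape(n, cout * k * k, h * wd)
        if x.requires_grad:
            x._accum(np.matmul(wm, gcolm).reshape(x.data.shape))
        if w.requires_grad:
            dw = np.matmul(xm, gcolm.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(out_data, req, parents, bwd)


def max_pool2d(x, k=2):
    """Non-overlapping k x k max pooling (spatial dims must divide k)."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
    oh, ow = h // k, w // k
    win = x.data.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, oh, ow, k * k)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gwin = np.zeros((n, c, oh, ow, k * k), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(n, c, h, w))

    return Tensor(out_data, x.requires_grad, (x,), bwd)
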