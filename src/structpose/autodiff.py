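"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operator set the pose network needs:
broadcast arithmetic, matmul with stacked batch dimensions, elementwise
nonlinearities, reductions, shape manipulation, gather/scatter indexing,
2-D convolution (im2col), and bilinear grid sampling with gradients with
respect to both features and sampling coordinates.

All tensors are float64 by default; the networks here are small enough
that double precision costs little and removes a whole class of
numerical-tolerance questions from the tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(p for p in _prev if p.requires_grad)
        self.name = name
        if self._prev:
            self.requires_grad = True

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None, free_graph: bool = True):
        """Reverse-mode sweep. With ``free_graph`` (default) the tape is
        dismantled as it is consumed: closures and parent links are
        dropped so the (cyclic) graph is reclaimed by refcounting
        immediately instead of waiting for the garbage collector."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if free_graph and node._prev:
                node._backward = None
                node._prev = ()
                node.grad = None  # interior grads are never read back

    def detach(self):
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient flows only inside the interval."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data > lo) & (self.data < hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                g = np.expand_dims(g, tuple(sorted(axes)))
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accum(gx)

        out._backward = bw
        return out

    # -- softmax over an axis ----------------------------------------------

    def softmax(self, axis=-1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def stack(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Convolution


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (b, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(cols).reshape(b, c * kh * kw, oh * ow), (oh, ow)


def _col2im(gcols: np.ndarray, xshape, kh, kw, stride, pad):
    b, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    g = gcols.reshape(b, c, kh, kw, oh, ow)
    gx = np.zeros((b, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad : hp - pad, pad : wp - pad]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square stride/pad."""
    x = Tensor._wrap(x)
    cout, cin, kh, kw = w.shape
    cols, (oh, ow) = _im2col(x.data, kh, kw, stride, pad)
    wr = w.data.reshape(cout, -1)
    out_data = np.einsum("ok,bkn->bon", wr, cols, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data.reshape(x.shape[0], cout, oh, ow), _prev=prev)

    def bw(g):
        gr = g.reshape(x.shape[0], cout, oh * ow)
        if w.requires_grad:
            gw = np.einsum("bon,bkn->ok", gr, cols, optimize=True)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(gr.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("ok,bon->bkn", wr, gr, optimize=True)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride, pad))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Bilinear sampling


def grid_sample(x: Tensor, coords: Tensor) -> Tensor:
    """Bilinear sampling with border clamping.

    x: (B, C, H, W) feature map; coords: (B, N, 2) pixel coordinates in
    (col, row) order on x's own grid. Returns (B, C, N). Differentiable in
    both the features and the coordinates; at clamped (out-of-grid)
    coordinates the coordinate gradient is zero.
    """
    x = Tensor._wrap(x)
    coords = Tensor._wrap(coords)
    bsz, c, h, w = x.shape
    cx = coords.data[..., 0]
    cy = coords.data[..., 1]
    in_x = (cx > 0) & (cx < w - 1)
    in_y = (cy > 0) & (cy < h - 1)
    cxc = np.clip(cx, 0.0, w - 1.0)
    cyc = np.clip(cy, 0.0, h - 1.0)
    x0 = np.clip(np.floor(cxc).astype(np.intp), 0, max(w - 2, 0))
    y0 = np.clip(np.floor(cyc).astype(np.intp), 0, max(h - 2, 0))
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    tx = cxc - x0
    ty = cyc - y0

    xf = x.data.reshape(bsz, c, h * w)
    idx = [y0 * w + x0, y0 * w + x1, y1 * w + x0, y1 * w + x1]
    vals = [np.take_along_axis(xf, i[:, None, :], axis=2) for i in idx]  # (B,C,N)
    w00 = (1 - ty) * (1 - tx)
    w01 = (1 - ty) * tx
    w10 = ty * (1 - tx)
    w11 = ty * tx
    weights = [w00, w01, w10, w11]
    out_data = sum(v * wt[:, None, :] for v, wt in zip(vals, weights))
    out = Tensor(out_data, _prev=(x, coords))

    def bw(g):
        if x.requires_grad:
            gxf = np.zeros_like(xf)
            bb = np.arange(bsz)[:, None, None]
            cc = np.arange(c)[None, :, None]
            for i, wt in zip(idx, weights):
                np.add.at(gxf, (bb, cc, i[:, None, :]), g * wt[:, None, :])
            x._accum(gxf.reshape(x.shape))
        if coords.requires_grad:
            v00, v01, v10, v11 = vals
            dvx = (1 - ty)[:, None, :] * (v01 - v00) + ty[:, None, :] * (v11 - v10)
            dvy = (1 - tx)[:, None, :] * (v10 - v00) + tx[:, None, :] * (v11 - v01)
            gx = (g * dvx).sum(axis=1) * in_x
            gy = (g * dvy).sum(axis=1) * in_y
            coords._accum(np.stack([gx, gy], axis=-1))

    out._backward = bw
    return out
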