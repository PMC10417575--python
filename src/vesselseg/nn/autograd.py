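"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation networks need: broadcasted
arithmetic, matmul, elementwise nonlinearities, reductions, channel
concatenation, 2-D convolution (im2col), 2-D transposed convolution with
kernel == stride, and 2x2 max pooling.  Arrays keep whatever float dtype
they come in with, so gradient checks can run in float64 while training
runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "maxpool2d"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return _wrap(other) * self ** -1.0

    def __pow__(self, p):
        p = float(p)
        out_data = self.data ** p

        def bwd(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = _wrap(other)
        out_data = self.data @ other.data

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * out_data,))

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,)
        )

    def relu(self):
        mask = self.data > 0
        return Tensor(
            np.where(mask, self.data, 0.0),
            parents=(self,),
            backward=lambda g: (g * mask,),
        )

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(
            out_data,
            parents=(self,),
            backward=lambda g: (g * out_data * (1.0 - out_data),),
        )

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return Tensor(
            out_data,
            parents=(self,),
            backward=lambda g: (g.reshape(self.shape),),
        )


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# --------------------------------------------------------------------- conv
def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _same_pad(k):
    # asymmetric for even kernels: left/top gets the smaller half
    return (k - 1) // 2, k // 2


def _im2col(xp, kh, kw, sh, sw):
    n, c, h, w = xp.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * sh, s3 * sw)
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow), oh, ow


def conv2d(x, weight, bias=None, stride=1, padding="same"):
    """2-D cross-correlation, NCHW layout, weight (F, C, kh, kw)."""
    x, weight = _wrap(x), _wrap(weight)
    fo, ci, kh, kw = weight.shape
    sh, sw = _pair(stride)
    if padding == "same":
        (pt, pb), (pl, pr) = _same_pad(kh), _same_pad(kw)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        pt = pb = pl = pr = int(padding)
    xd = x.data
    if pt or pb or pl or pr:
        xp = np.pad(xd, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    else:
        xp = xd
    cols, oh, ow = _im2col(xp, kh, kw, sh, sw)
    wm = weight.data.reshape(fo, -1)
    out = np.matmul(wm[None], cols).reshape(xd.shape[0], fo, oh, ow)

    parents = [x, weight]
    if bias is not None:
        bias = _wrap(bias)
        out = out + bias.data.reshape(1, fo, 1, 1)
        parents.append(bias)

    def bwd(g):
        n = xd.shape[0]
        g2 = g.reshape(n, fo, oh * ow)
        gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
        dcols = np.matmul(wm.T[None], g2).reshape(n, ci, kh, kw, oh, ow)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += dcols[
                    :, :, i, j
                ]
        h, w = xd.shape[2], xd.shape[3]
        gx = dxp[:, :, pt : pt + h, pl : pl + w]
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor(out, parents=tuple(parents), backward=bwd)


def conv_transpose2d(x, weight, bias=None, stride=2):
    """Transposed convolution with kernel == stride (exact upsampling).

    weight has shape (C_in, C_out, k, k); output spatial size is input * k.
    """
    x, weight = _wrap(x), _wrap(weight)
    ci, co, kh, kw = weight.shape
    s = int(stride)
    if kh != s or kw != s:
        raise ValueError("conv_transpose2d requires kernel == stride")
    n, c, h, w = x.shape
    out = np.zeros((n, co, h * s, w * s), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i::s, j::s] = np.einsum(
                "nchw,cf->nfhw", x.data, weight.data[:, :, i, j], optimize=True
            )
    parents = [x, weight]
    if bias is not None:
        bias = _wrap(bias)
        out = out + bias.data.reshape(1, co, 1, 1)
        parents.append(bias)

    def bwd(g):
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(weight.data)
        for i in range(kh):
            for j in range(kw):
                gij = g[:, :, i::s, j::s]
                gx += np.einsum(
                    "nfhw,cf->nchw", gij, weight.data[:, :, i, j], optimize=True
                )
                gw[:, :, i, j] = np.einsum(
                    "nchw,nfhw->cf", x.data, gij, optimize=True
                )
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor(out, parents=tuple(parents), backward=bwd)


def maxpool2d(x, k=2):
    x = _wrap(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial size ({h},{w}) not divisible by {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // k, w // k, k * k)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return (gr.reshape(n, c, h, w),)

    return Tensor(out, parents=(x,), backward=bwd)
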