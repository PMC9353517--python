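"""Minimal reverse-mode autodiff core on numpy arrays.

Everything the segmentation model needs — and nothing more — is implemented
here: broadcast-aware arithmetic, matmul, im2col convolutions, pooling,
bilinear RoI alignment, pixel shuffle and the fused stable losses. Tensors
wrap a numpy array; calling :meth:`Tensor.backward` runs the tape in reverse
topological order. Single-threaded CPU semantics, deterministic given
deterministic inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "conv1d_channels",
    "max_pool2d",
    "global_avg_pool",
    "pixel_shuffle",
    "upsample_nearest",
    "roi_align",
    "bce_with_logits",
    "softmax_cross_entropy",
    "smooth_l1",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if p.requires_grad:
                        stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division only by constants")
        return self * (1.0 / other)

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bwd
        return out

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    # -- reductions & elementwise -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bwd
        return out

    def sigmoid(self):
        s = _sigmoid(self.data)
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bwd
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


# -- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    """Return (cols, (Ho, Wo), xp_shape). cols has shape (N, C*kh*kw, Ho*Wo)."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, kh, kw, Ho, Wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
        writeable=False,
    )
    cols = win.reshape(N, C * kh * kw, Ho * Wo) if win.flags.c_contiguous else \
        np.ascontiguousarray(win).reshape(N, C * kh * kw, Ho * Wo)
    return cols, (Ho, Wo), xp.shape


def _col_indices(C, kh, kw, Ho, Wo, sh, sw):
    """Padded-array (c, i, j) index triplets aligned with im2col layout."""
    c = np.repeat(np.arange(C), kh * kw)
    di = np.tile(np.repeat(np.arange(kh), kw), C)
    dj = np.tile(np.arange(kw), C * kh)
    oi = np.repeat(np.arange(Ho) * sh, Wo)
    oj = np.tile(np.arange(Wo) * sw, Ho)
    i = di[:, None] + oi[None, :]        # (C*kh*kw, Ho*Wo)
    j = dj[:, None] + oj[None, :]
    return c[:, None], i, j


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    O, C, kh, kw = weight.data.shape
    N = x.data.shape[0]
    cols, (Ho, Wo), xp_shape = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    Wm = weight.data.reshape(O, C * kh * kw)
    out = np.matmul(Wm, cols)            # (N, O, Ho*Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    res = Tensor(out.reshape(N, O, Ho, Wo),
                 any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gf = g.reshape(N, O, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if weight.requires_grad:
            dW = np.tensordot(gf, cols, axes=([0, 2], [0, 2]))
            weight._accum(dW.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.matmul(Wm.T, gf)  # (N, C*kh*kw, Ho*Wo)
            dxp = np.zeros(xp_shape, dtype=x.data.dtype)
            cidx, iidx, jidx = _col_indices(C, kh, kw, Ho, Wo, stride, stride)
            np.add.at(dxp, (slice(None), cidx, iidx, jidx), dcols)
            H, W = x.data.shape[2:]
            x._accum(dxp[:, :, padding:padding + H, padding:padding + W])

    res._backward = bwd
    return res


def conv1d_channels(v: Tensor, kernel: Tensor) -> Tensor:
    """1-D convolution of a per-image channel vector (N, C) with an odd-width
    kernel (k,), zero padding (k-1)/2, no bias.  Used by the channel-attention
    gate: each channel attends to its k nearest neighbours."""
    k = kernel.data.shape[0]
    pad = (k - 1) // 2
    N, C = v.data.shape
    vp = np.pad(v.data, ((0, 0), (pad, pad)))
    s = vp.strides
    win = np.lib.stride_tricks.as_strided(
        vp, shape=(N, C, k), strides=(s[0], s[1], s[1]), writeable=False)
    out = win @ kernel.data
    res = Tensor(out, v.requires_grad or kernel.requires_grad, (v, kernel))

    def bwd(g):
        if kernel.requires_grad:
            kernel._accum(np.einsum("nc,nck->k", g, win))
        if v.requires_grad:
            dvp = np.zeros_like(vp)
            offs = np.arange(k)
            idx = np.arange(C)[:, None] + offs[None, :]
            np.add.at(dvp, (slice(None), idx), g[:, :, None] * kernel.data[None, None, :])
            v._accum(dvp[:, pad:pad + C])

    res._backward = bwd
    return res


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    N, C, H, W = x.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(N, C, Ho, Wo, kernel, kernel),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False)
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    res = Tensor(out, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((N, C, Hp, Wp), dtype=x.data.dtype)
        pi = (np.arange(Ho) * stride)[None, None, :, None] + arg // kernel
        pj = (np.arange(Wo) * stride)[None, None, None, :] + arg % kernel
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        np.add.at(dxp, (n_idx, c_idx, pi, pj), g)
        x._accum(dxp[:, :, padding:padding + H, padding:padding + W])

    res._backward = bwd
    return res


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""
    return x.mean(axis=(2, 3))


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Periodic channel-to-space rearrangement: (N, C*r^2, H, W) -> (N, C, H*r, W*r).

    Intermediate channel c*r*r + dy*r + dx lands on output pixel (y*r+dy, x*r+dx)
    of channel c — the sub-pixel convolution layout.
    """
    N, Cr2, H, W = x.shape
    C = Cr2 // (r * r)
    if C * r * r != Cr2:
        raise ValueError(f"channel count {Cr2} not divisible by r^2={r * r}")
    t = x.reshape(N, C, r, r, H, W)
    t = t.transpose((0, 1, 4, 2, 5, 3))          # N, C, H, r, W, r
    return t.reshape(N, C, H * r, W * r)


def upsample_nearest(x: Tensor, r: int) -> Tensor:
    out = Tensor(np.repeat(np.repeat(x.data, r, axis=2), r, axis=3),
                 x.requires_grad, (x,))
    N, C, H, W = x.data.shape

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(N, C, H, r, W, r).sum(axis=(3, 5)))

    out._backward = bwd
    return out


# -- RoIAlign -------------------------------------------------------------

def roi_align(features: Tensor, boxes: np.ndarray, batch_idx: np.ndarray,
              output_size: int, spatial_scale: float,
              sampling_ratio: int = 2) -> Tensor:
    """Quantization-free bilinear pooling of boxes to a fixed grid.

    boxes: (R, 4) [x1, y1, x2, y2] in input-image pixels; batch_idx: (R,).
    Uses the half-pixel-aligned convention (continuous coordinate c maps to
    sample position c * scale - 0.5); each output cell averages
    sampling_ratio^2 bilinear samples.  Gradients flow to `features` only.
    """
    N, C, H, W = features.data.shape
    R = boxes.shape[0]
    P, S = output_size, sampling_ratio
    out_dtype = features.data.dtype
    if R == 0:
        return Tensor(np.zeros((0, C, P, P), dtype=out_dtype),
                      features.requires_grad, (features,))
    x1 = boxes[:, 0] * spatial_scale - 0.5
    y1 = boxes[:, 1] * spatial_scale - 0.5
    x2 = boxes[:, 2] * spatial_scale - 0.5
    y2 = boxes[:, 3] * spatial_scale - 0.5
    bw = np.maximum(x2 - x1, 1e-6)
    bh = np.maximum(y2 - y1, 1e-6)
    # sample positions: P cells, S sub-samples per cell per axis
    gx = (np.arange(P * S) + 0.5) / S / P          # fractions in [0,1]
    sx = x1[:, None] + bw[:, None] * gx[None, :]   # (R, P*S)
    sy = y1[:, None] + bh[:, None] * gx[None, :]
    sx = np.clip(sx, 0, W - 1)
    sy = np.clip(sy, 0, H - 1)
    x0 = np.floor(sx).astype(np.int64)
    y0 = np.floor(sy).astype(np.int64)
    x0 = np.minimum(x0, W - 2) if W > 1 else x0 * 0
    y0 = np.minimum(y0, H - 2) if H > 1 else y0 * 0
    fx = sx - x0
    fy = sy - y0
    # gather: value (R, C, P*S(y), P*S(x))
    b = batch_idx[:, None, None]
    yy0 = y0[:, :, None]
    xx0 = x0[:, None, :]
    fyy = fy[:, :, None]
    fxx = fx[:, None, :]
    f = features.data
    v00 = f[b, :, yy0, xx0]          # (R, P*S, P*S, C)
    v01 = f[b, :, yy0, xx0 + (1 if W > 1 else 0)]
    v10 = f[b, :, yy0 + (1 if H > 1 else 0), xx0]
    v11 = f[b, :, yy0 + (1 if H > 1 else 0), xx0 + (1 if W > 1 else 0)]
    w00 = ((1 - fyy) * (1 - fxx))[..., None]
    w01 = ((1 - fyy) * fxx)[..., None]
    w10 = (fyy * (1 - fxx))[..., None]
    w11 = (fyy * fxx)[..., None]
    val = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11   # (R, PS, PS, C)
    val = val.reshape(R, P, S, P, S, C).mean(axis=(2, 4))  # (R, P, P, C)
    out = np.ascontiguousarray(val.transpose(0, 3, 1, 2))
    res = Tensor(out.astype(out_dtype, copy=False), features.requires_grad, (features,))

    def bwd(g):
        if not features.requires_grad:
            return
        gval = g.transpose(0, 2, 3, 1)[:, :, None, :, None, :] \
            * (1.0 / (S * S))
        gval = np.broadcast_to(gval, (R, P, S, P, S, C)).reshape(R, P * S, P * S, C)
        df = np.zeros_like(f)
        xs1 = xx0 + (1 if W > 1 else 0)
        ys1 = yy0 + (1 if H > 1 else 0)
        np.add.at(df, (b, slice(None), yy0, xx0), gval * w00)
        np.add.at(df, (b, slice(None), yy0, xs1), gval * w01)
        np.add.at(df, (b, slice(None), ys1, xx0), gval * w10)
        np.add.at(df, (b, slice(None), ys1, xs1), gval * w11)
        features._accum(df)

    res._backward = bwd
    return res


# -- losses ---------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray, reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    t = logits.data
    y = np.asarray(targets, dtype=t.dtype)
    loss = np.maximum(t, 0) - t * y + np.log1p(np.exp(-np.abs(t)))
    n = loss.size if reduction == "mean" else 1.0
    out = Tensor(np.asarray(loss.sum() / n, dtype=t.dtype), logits.requires_grad, (logits,))

    def bwd(g):
        if logits.requires_grad:
            logits._accum(g * (_sigmoid(t) - y) / n)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels (N,)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    idx = (np.arange(n), np.asarray(labels))
    loss = -(np.log(np.maximum(p[idx], 1e-300))).mean()
    out = Tensor(np.asarray(loss, dtype=z.dtype), logits.requires_grad, (logits,))

    def bwd(g):
        if logits.requires_grad:
            dp = p.copy()
            dp[idx] -= 1.0
            logits._accum(g * dp / n)

    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0,
              reduction: str = "mean") -> Tensor:
    """Huber-style smooth-L1: quadratic below beta, linear above."""
    d = pred.data - np.asarray(target, dtype=pred.data.dtype)
    ad = np.abs(d)
    if beta > 0:
        loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    else:
        loss = ad
    n = loss.size if reduction == "mean" else 1.0
    out = Tensor(np.asarray(loss.sum() / max(n, 1), dtype=pred.data.dtype),
                 pred.requires_grad, (pred,))

    def bwd(g):
        if pred.requires_grad:
            if beta > 0:
                dd = np.where(ad < beta, d / beta, np.sign(d))
            else:
                dd = np.sign(d)
            pred._accum(g * dd / max(n, 1))

    out._backward = bwd
    return out
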