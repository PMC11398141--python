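"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the tensor operations the segmentation network needs:
elementwise arithmetic with broadcasting, the usual nonlinearities,
axis reductions, concatenation, 2-D convolution (dense and depthwise,
with dilation), 2x2 transposed convolution, and 2x2 max pooling.

All operations preserve the dtype of their inputs, so the same graph can
be run in float32 for training and float64 when comparing against
high-precision oracles.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A NumPy array plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- inspection -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError(
                    f"backward() without an explicit gradient requires a "
                    f"scalar, got shape {self.data.shape}")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(-self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x))


def _accumulate(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    g = np.asarray(g, dtype=t.data.dtype)
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient `g` down to `shape` (the reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    # scalar fast path: keep Python numbers out of the graph so they do
    # not promote float32 tensors to float64
    if isinstance(b, (int, float)) or isinstance(a, (int, float)):
        if isinstance(a, (int, float)):
            a, b = b, a
        a = _as_tensor(a)
        s = a.data.dtype.type(b)
        out_data = a.data + s

        def backward_s(g):
            _accumulate(a, g)

        return _make(out_data, (a,), backward_s)

    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)) or isinstance(a, (int, float)):
        if isinstance(a, (int, float)):
            a, b = b, a
        a = _as_tensor(a)
        s = a.data.dtype.type(b)
        out_data = a.data * s

        def backward_s(g):
            _accumulate(a, g * s)

        return _make(out_data, (a,), backward_s)

    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        return mul(a, 1.0 / b)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        _accumulate(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        _accumulate(a, g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        _accumulate(a, g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; gradient is passed only where unclipped."""
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accumulate(a, g * mask)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0)

    def backward(g):
        _accumulate(a, g * mask)

    return _make(out_data, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    neg = np.expm1(np.minimum(a.data, 0.0)) * alpha
    out_data = np.where(a.data > 0, a.data, neg)

    def backward(g):
        _accumulate(a, g * np.where(a.data > 0, 1.0, neg + alpha))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    from scipy.special import expit

    a = _as_tensor(a)
    out_data = expit(a.data)

    def backward(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


# -- reductions and shape ops ---------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accumulate(a, np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
    s = tsum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / float(n))


def tmax(a, axis: int, keepdims=False) -> Tensor:
    """Max along one axis; gradient routed to the first maximal element."""
    a = _as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), g, axis=axis)
        _accumulate(a, ga)

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accumulate(a, g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def broadcast_hw(a, h: int, w: int) -> Tensor:
    """Broadcast a (B, C, 1, 1) map to (B, C, h, w)."""
    a = _as_tensor(a)
    if a.shape[2:] != (1, 1):
        raise ValueError(f"expected trailing dims (1,1), got {a.shape}")
    out_data = np.broadcast_to(a.data, a.shape[:2] + (h, w)).copy()

    def backward(g):
        _accumulate(a, g.sum(axis=(2, 3), keepdims=True))

    return _make(out_data, (a,), backward)


def batchnorm2d(x, gamma, beta, eps: float = 1e-5):
    """Fused batch normalization over (B, H, W) per channel (training mode).

    gamma/beta are (1, C, 1, 1).  Returns (out, batch_mean, batch_var); the
    statistics are plain arrays for the caller's running-average update.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + x.data.dtype.type(eps))
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        gbeta = g.sum(axis=axes, keepdims=True)
        ggamma = (g * xhat).sum(axis=axes, keepdims=True)
        _accumulate(beta, gbeta)
        _accumulate(gamma, ggamma)
        if x.requires_grad or x._parents:
            gx = (gamma.data * inv) * (
                g - gbeta / n - xhat * (ggamma / n))
            _accumulate(x, gx)

    out = _make(out_data, (x, gamma, beta), backward)
    return out, mu, var


# -- convolution family ----------------------------------------------------

def conv2d(x, w, b=None, dilation: int = 1, padding: int | None = None) -> Tensor:
    """2-D cross-correlation, stride 1.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,) or None.
    `padding=None` selects same-size output: dilation*(k-1)//2 (odd k only).
    Implemented as a loop over the k*k kernel taps, each tap a GEMM, which
    keeps memory low and feeds BLAS well.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cw, k, k2 = w.shape
    if k != k2:
        raise ValueError("only square kernels are supported")
    if k % 2 == 0:
        raise ValueError(f"even kernel size {k} is unsupported")
    if Cw != Cin:
        raise ValueError(
            f"channel mismatch: input has {Cin} channels but the kernel "
            f"expects {Cw}")
    if padding is None:
        padding = dilation * (k - 1) // 2

    cols, (Ho, Wo) = _im2col(x.data, k, dilation, padding)
    w_mat = w.data.reshape(Cout, Cin * k * k)
    out_data = np.ascontiguousarray(
        (cols @ w_mat.T).reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2))
    bt = None
    if b is not None:
        bt = _as_tensor(b)
        out_data = out_data + bt.data.reshape(1, Cout, 1, 1)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            B * Ho * Wo, Cout)
        _accumulate(w, (gm.T @ cols).reshape(w.shape))
        if x.requires_grad or x._parents:
            # grad wrt input = correlation of the output grad with the
            # spatially flipped, channel-transposed kernel
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            wf_mat = np.ascontiguousarray(wf).reshape(Cin, Cout * k * k)
            gcols, (Hg, Wg) = _im2col(g, k, dilation,
                                      dilation * (k - 1) - padding)
            gx = np.ascontiguousarray(
                (gcols @ wf_mat.T).reshape(B, Hg, Wg, Cin).transpose(
                    0, 3, 1, 2))
            _accumulate(x, gx)
        if bt is not None:
            _accumulate(bt, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out_data, parents, backward)


def _im2col(data: np.ndarray, k: int, dilation: int, padding: int):
    """Unfold (B,C,H,W) into (B*Ho*Wo, C*k*k) patch rows."""
    B, C = data.shape[:2]
    if padding:
        data = np.pad(data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding)))
    Ho = data.shape[2] - dilation * (k - 1)
    Wo = data.shape[3] - dilation * (k - 1)
    if k == 1:
        cols = np.ascontiguousarray(data.transpose(0, 2, 3, 1)).reshape(
            B * Ho * Wo, C)
    else:
        ke = dilation * (k - 1) + 1
        view = np.lib.stride_tricks.sliding_window_view(
            data, (ke, ke), axis=(2, 3))[:, :, :, :, ::dilation, ::dilation]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * Ho * Wo, C * k * k)
    return cols, (Ho, Wo)


def depthwise_conv2d(x, w, b=None, dilation: int = 1,
                     padding: int | None = None) -> Tensor:
    """Per-channel 2-D cross-correlation, stride 1.

    x: (B, C, H, W); w: (C, k, k); b: (C,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, C, H, W = x.shape
    Cw, k, k2 = w.shape
    if k != k2 or k % 2 == 0:
        raise ValueError(f"even or non-square kernel size {k}x{k2} unsupported")
    if Cw != C:
        raise ValueError(
            f"channel mismatch: input has {C} channels but the depthwise "
            f"kernel expects {Cw}")
    if padding is None:
        padding = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = xp.shape[2] - dilation * (k - 1)
    Wo = xp.shape[3] - dilation * (k - 1)
    out_data = np.zeros((B, C, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i * dilation:i * dilation + Ho,
                    j * dilation:j * dilation + Wo]
            out_data += w.data[None, :, i, j, None, None] * xs
    bt = None
    if b is not None:
        bt = _as_tensor(b)
        out_data = out_data + bt.data.reshape(1, C, 1, 1)

    def backward(g):
        need_x = x.requires_grad or x._parents
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * dilation:i * dilation + Ho,
                        j * dilation:j * dilation + Wo]
                gw[:, i, j] = (g * xs).sum(axis=(0, 2, 3))
                if need_x:
                    gxp[:, :, i * dilation:i * dilation + Ho,
                        j * dilation:j * dilation + Wo] += \
                        w.data[None, :, i, j, None, None] * g
        _accumulate(w, gw)
        if need_x:
            if padding:
                _accumulate(x, gxp[:, :, padding:padding + H, padding:padding + W])
            else:
                _accumulate(x, gxp)
        if bt is not None:
            _accumulate(bt, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out_data, parents, backward)


def conv_transpose2d_2x2(x, w, b=None) -> Tensor:
    """Transposed convolution with 2x2 kernel, stride 2 (feature upsampling).

    x: (B, Cin, H, W) -> (B, Cout, 2H, 2W); w: (Cin, Cout, 2, 2).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, Cin, H, W = x.shape
    Cw, Cout, k, k2 = w.shape
    if (k, k2) != (2, 2):
        raise ValueError("only 2x2 stride-2 transposed convolution is supported")
    if Cw != Cin:
        raise ValueError(
            f"channel mismatch: input has {Cin} channels but the kernel "
            f"expects {Cw}")
    xm = x.data.reshape(B, Cin, H * W)
    out_data = np.empty((B, Cout, 2 * H, 2 * W), dtype=x.dtype)
    for i in range(2):
        for j in range(2):
            oij = np.matmul(w.data[:, :, i, j].T, xm).reshape(B, Cout, H, W)
            out_data[:, :, i::2, j::2] = oij
    bt = None
    if b is not None:
        bt = _as_tensor(b)
        out_data = out_data + bt.data.reshape(1, Cout, 1, 1)

    def backward(g):
        gw = np.zeros_like(w.data)
        gx = np.zeros_like(x.data) if (x.requires_grad or x._parents) else None
        for i in range(2):
            for j in range(2):
                gij = np.ascontiguousarray(g[:, :, i::2, j::2]).reshape(
                    B, Cout, H * W)
                gw[:, :, i, j] = np.tensordot(xm, gij, axes=([0, 2], [0, 2]))
                if gx is not None:
                    gx += np.matmul(w.data[:, :, i, j], gij).reshape(
                        B, Cin, H, W)
        _accumulate(w, gw)
        if gx is not None:
            _accumulate(x, gx)
        if bt is not None:
            _accumulate(bt, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(out_data, parents, backward)


def maxpool2d_2x2(x) -> Tensor:
    """2x2 max pooling, stride 2; H and W must be even."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"spatial dims ({H},{W}) must be even for 2x2 pooling")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accumulate(x, np.ascontiguousarray(gr).reshape(B, C, H, W))

    return _make(out_data, (x,), backward)
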