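"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the restoration network needs:
broadcast arithmetic, batched matmul, 3D convolution (im2col), trilinear
2x upsampling, reductions, reshapes and the usual nonlinearities.
Gradients are verified against central finite differences in the test
suite. All data is float32.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode; saves memory)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """A numpy array plus the closure needed to backpropagate into it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self._grad_shared = False

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        # First accumulation keeps a reference (g may be a view shared with
        # another node); only a second accumulation allocates.
        if self.grad is None:
            self.grad = g if g.dtype == np.float32 else g.astype(np.float32)
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(_ensure(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic -------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _ensure(a)
    if isinstance(p, Tensor):
        raise TypeError("only scalar exponents are supported")
    data = a.data ** p

    def backward(g):
        a._accum(_unbroadcast(g * p * a.data ** (p - 1.0), a.shape))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.shape))
        b._accum(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def exp(a) -> Tensor:
    a = _ensure(a)
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def abs_(a) -> Tensor:
    a = _ensure(a)
    data = np.abs(a.data)

    def backward(g):
        a._accum(g * np.sign(a.data))

    return _make(data, (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0
    data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        a._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

    return _make(data, (a,), backward)


def gelu(a) -> Tensor:
    """tanh-approximate GELU with an analytic derivative."""
    a = _ensure(a)
    c = np.float32(np.sqrt(2.0 / np.pi))
    x = a.data
    inner = c * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    data = 0.5 * x * (1.0 + t)

    def backward(g):
        dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
        local = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
        a._accum(g * local.astype(np.float32))

    return _make(data, (a,), backward)


# -- shape ops --------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.shape))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _ensure(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _make(data, tuple(tensors), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).astype(np.float32))

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i] for i in axes]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax as a fused primitive."""
    a = _ensure(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    np.exp(shifted, out=shifted)
    shifted /= shifted.sum(axis=axis, keepdims=True)
    y = shifted

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accum(y * (g - dot))

    return _make(y, (a,), backward)


def index_axis0(a, i: int) -> Tensor:
    """Select slice ``a[i]`` along the leading axis."""
    a = _ensure(a)
    data = a.data[i]

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[i] = g
        a._accum(ga)

    return _make(data, (a,), backward)


# -- convolution ------------------------------------------------------------

try:  # JIT-compiled patch extraction/accumulation; numpy fallback below
    from numba import njit as _njit

    @_njit(cache=True)
    def _im2col_nb(xp, kd, kh, kw, sd, sh, sw, Do, Ho, Wo, out):
        N, C, Dp, Hp, Wp = xp.shape
        K = kd * kh * kw
        for n in range(N):
            for do in range(Do):
                for ho in range(Ho):
                    for wo in range(Wo):
                        l = (do * Ho + ho) * Wo + wo
                        for c in range(C):
                            base = c * K
                            for i in range(kd):
                                for j in range(kh):
                                    for k in range(kw):
                                        out[n, l, base + (i * kh + j) * kw + k] = \
                                            xp[n, c, do * sd + i, ho * sh + j,
                                               wo * sw + k]

    @_njit(cache=True)
    def _col2im_nb(gcols, kd, kh, kw, sd, sh, sw, Do, Ho, Wo, gxp):
        N, C, Dp, Hp, Wp = gxp.shape
        K = kd * kh * kw
        for n in range(N):
            for do in range(Do):
                for ho in range(Ho):
                    for wo in range(Wo):
                        l = (do * Ho + ho) * Wo + wo
                        for c in range(C):
                            base = c * K
                            for i in range(kd):
                                for j in range(kh):
                                    for k in range(kw):
                                        gxp[n, c, do * sd + i, ho * sh + j,
                                            wo * sw + k] += \
                                            gcols[n, l, base + (i * kh + j) * kw + k]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _triple(v):
    return (v, v, v) if isinstance(v, int) else tuple(v)


def conv3d(x, w, b=None, stride=1, padding=0) -> Tensor:
    """3D cross-correlation. x: (N,C,D,H,W), w: (F,C,kd,kh,kw), b: (F,)."""
    x, w = _ensure(x), _ensure(w)
    if b is not None:
        b = _ensure(b)
    sd, sh, sw = _triple(stride)
    pd, ph, pw = _triple(padding)
    N, C, D, H, W = x.shape
    F, Cw, kd, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    if _HAVE_NUMBA:
        cols = np.empty((N, Do * Ho * Wo, C * kd * kh * kw), dtype=np.float32)
        _im2col_nb(xp, kd, kh, kw, sd, sh, sw, Do, Ho, Wo, cols)
    else:
        view = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        view = view[:, :, ::sd, ::sh, ::sw]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(N, Do * Ho * Wo, C * kd * kh * kw)
    wmat = w.data.reshape(F, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    data = out.transpose(0, 2, 1).reshape(N, F, Do, Ho, Wo)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        L = Do * Ho * Wo
        gmat = np.ascontiguousarray(
            g.reshape(N, F, L).transpose(0, 2, 1)).reshape(N * L, F)
        gw = gmat.T @ cols.reshape(N * L, -1)
        w._accum(gw.reshape(w.shape))
        if b is not None:
            b._accum(gmat.sum(axis=0))
        gcols = (gmat @ wmat).reshape(N, L, -1)  # (N,L,C*k^3)
        gxp = np.zeros_like(xp)
        if _HAVE_NUMBA:
            _col2im_nb(gcols, kd, kh, kw, sd, sh, sw, Do, Ho, Wo, gxp)
        else:
            gc = gcols.reshape(N, Do, Ho, Wo, C, kd, kh, kw)
            for i in range(kd):
                for j in range(kh):
                    for l in range(kw):
                        gxp[:, :, i:i + sd * Do:sd, j:j + sh * Ho:sh,
                            l:l + sw * Wo:sw] += gc[:, :, :, :, :, i, j, l
                                                    ].transpose(0, 4, 1, 2, 3)
        gx = gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]
        x._accum(gx)

    return _make(data, parents, backward)


# -- trilinear upsampling ---------------------------------------------------


def _up2_last(a: np.ndarray) -> np.ndarray:
    n = a.shape[-1]
    left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    y = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    y[..., 0::2] = 0.25 * left + 0.75 * a
    y[..., 1::2] = 0.75 * a + 0.25 * right
    return y


def _up2_last_adjoint(gy: np.ndarray) -> np.ndarray:
    e = gy[..., 0::2]
    o = gy[..., 1::2]
    gx = (0.75 * (e + o)).astype(gy.dtype)
    gx[..., :-1] += 0.25 * e[..., 1:]
    gx[..., 0] += 0.25 * e[..., 0]
    gx[..., 1:] += 0.25 * o[..., :-1]
    gx[..., -1] += 0.25 * o[..., -1]
    return gx


def upsample2x(x) -> Tensor:
    """Trilinear 2x upsampling of (N,C,D,H,W), separable per axis."""
    x = _ensure(x)
    data = x.data
    for ax in (2, 3, 4):
        data = np.moveaxis(_up2_last(np.moveaxis(data, ax, -1)), -1, ax)

    def backward(g):
        for ax in (4, 3, 2):
            g = np.moveaxis(_up2_last_adjoint(np.moveaxis(g, ax, -1)), -1, ax)
        x._accum(g)

    return _make(data, (x,), backward)
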