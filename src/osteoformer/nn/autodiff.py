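"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine providing exactly the operations the
segmentation models need: broadcast arithmetic, batched matmul, dense and
depthwise 2-D convolution, layer normalisation, softmax, GELU, bilinear
resampling, concatenation and a fused softmax cross-entropy.  Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "layer_norm",
    "gelu",
    "softmax",
    "bilinear_resize",
    "cross_entropy_logits",
]

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # copy lazily: adopt the array by reference first; allocate a fresh
        # owned buffer only if a second contribution arrives
        if grad.dtype != self.data.dtype:
            grad = grad.astype(self.data.dtype)
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- introspection --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd driver -------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars at this tensor's dtype to avoid float64 upcasts
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported; multiply by a reciprocal")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._coerce(other)
        if self.ndim > 2 and other.ndim > 2 and self.shape[:-2] != other.shape[:-2]:
            raise ValueError("batched matmul requires identical leading dimensions")

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
        x._accum(g * (cdf + x.data * pdf))

    return Tensor._make(x.data * cdf, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor._make(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then apply an affine transform."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        if gamma.requires_grad:
            red = tuple(range(g.ndim - 1))
            gamma._accum((g * xhat).sum(axis=red))
        if beta.requires_grad:
            red = tuple(range(g.ndim - 1))
            beta._accum(g.sum(axis=red))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum((dxhat - m1 - xhat * m2) * inv)

    return Tensor._make(xhat * gamma.data + beta.data, (x, gamma, beta), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation (NCHW).

    Computed tap-by-tap over the kernel window, which keeps memory at one
    feature map instead of the k*k-fold im2col blow-up: depthwise taps are
    fused multiply-adds, dense taps are single GEMMs.  Only depthwise
    (groups == channels) and dense (groups == 1) convolutions are supported,
    which covers every layer in the models.
    """
    B, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    if C != Cg * groups or O % groups:
        raise ValueError("channel/group mismatch in conv2d")
    if groups not in (1, C):
        raise ValueError("conv2d supports dense (groups=1) or depthwise (groups=C) only")
    depthwise = groups == C and C > 1
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1

    def taps(arr):
        for i in range(kh):
            for j in range(kw):
                yield i, j, arr[:, :, i:i + s * Ho:s, j:j + s * Wo:s]

    if depthwise:
        out = np.zeros((B, O, Ho, Wo), dtype=x.dtype)
        for i, j, xs in taps(xp):
            out += xs * w.data[None, :, 0, i, j, None, None]
    else:
        N = B * Ho * Wo
        out_f = np.zeros((N, O), dtype=x.dtype)
        for i, j, xs in taps(xp):
            xs_f = np.ascontiguousarray(xs.transpose(0, 2, 3, 1)).reshape(N, C)
            out_f += xs_f @ w.data[:, :, i, j].T
        out = out_f.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=g.dtype) if need_dx else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        if depthwise:
            for i, j, xs in taps(xp):
                if dw is not None:
                    dw[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                if need_dx:
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                        g * w.data[None, :, 0, i, j, None, None]
        else:
            N = B * Ho * Wo
            g_f = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N, O)
            for i, j, xs in taps(xp):
                xs_f = np.ascontiguousarray(xs.transpose(0, 2, 3, 1)).reshape(N, C)
                if dw is not None:
                    dw[:, :, i, j] = g_f.T @ xs_f
                if need_dx:
                    dxs = (g_f @ w.data[:, :, i, j]).reshape(B, Ho, Wo, C)
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dxs.transpose(0, 3, 1, 2)
        if dw is not None:
            w._accum(dw)
        if need_dx:
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    return Tensor._make(out, parents, backward)


def bilinear_resize(x: Tensor, out_side: int) -> Tensor:
    """Bilinear resize of an NCHW tensor to (out_side, out_side).

    Uses the half-pixel (align_corners=False) convention.
    """
    B, C, H, W = x.shape
    if (H, W) == (out_side, out_side):
        return x

    def grid(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(np.intp)
        i1 = np.minimum(i0 + 1, n_in - 1)
        t = (src - i0).astype(x.dtype)
        return i0, i1, t

    y0, y1, ty = grid(H, out_side)
    x0, x1, tx = grid(W, out_side)
    ty = ty[:, None]
    w00 = (1 - ty) * (1 - tx)
    w01 = (1 - ty) * tx
    w10 = ty * (1 - tx)
    w11 = ty * tx
    d = x.data
    out = (d[:, :, y0[:, None], x0] * w00 + d[:, :, y0[:, None], x1] * w01
           + d[:, :, y1[:, None], x0] * w10 + d[:, :, y1[:, None], x1] * w11)

    def backward(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), y0[:, None], x0), g * w00)
        np.add.at(dx, (slice(None), slice(None), y0[:, None], x1), g * w01)
        np.add.at(dx, (slice(None), slice(None), y1[:, None], x0), g * w10)
        np.add.at(dx, (slice(None), slice(None), y1[:, None], x1), g * w11)
        x._accum(dx)

    return Tensor._make(out, (x,), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; logits (B, C, ...), integer labels (B, ...)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = z - zmax - np.log(sez)
    lab = np.asarray(labels).astype(np.intp)
    picked = np.take_along_axis(logp, lab[:, None], axis=1)[:, 0]
    n = picked.size
    loss = -picked.sum() / n

    def backward(g):
        soft = ez / sez
        onehot = np.zeros_like(soft)
        np.put_along_axis(onehot, lab[:, None], 1.0, axis=1)
        logits._accum((soft - onehot) * (float(g) / n))

    return Tensor._make(np.asarray(loss, dtype=z.dtype), (logits,), backward)
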