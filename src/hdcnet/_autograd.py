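"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the primitives a small convolutional encoder–decoder
needs: 2-D (dilated) convolution, strided transposed convolution, 2x2 max
pooling, batch normalisation, element-wise arithmetic with broadcasting,
channel/spatial reductions, concatenation and slicing, ReLU/sigmoid, and a
mean-reduction suitable for losses.

Convolutions are evaluated as a sum of k*k shifted GEMMs (``np.einsum`` over
spatially shifted views), which keeps both the forward pass and the
hand-written vector-Jacobian products short and cache-friendly at the
feature-map sizes used for vessel segmentation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._vjp = vjp

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
            if node._vjp is None:
                continue
            for parent, pgrad in node._vjp(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), as_tensor(-1.0)))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# element-wise arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def vjp(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return Tensor(out_data, a.requires_grad or b.requires_grad, (a, b), vjp)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def vjp(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return Tensor(out_data, a.requires_grad or b.requires_grad, (a, b), vjp)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def vjp(g):
        return ((x, g * mask),)

    return Tensor(x.data * mask, x.requires_grad, (x,), vjp)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def vjp(g):
        return ((x, g * s * (1.0 - s)),)

    return Tensor(s, x.requires_grad, (x,), vjp)


def log(x: Tensor) -> Tensor:
    def vjp(g):
        return ((x, g / x.data),)

    return Tensor(np.log(x.data), x.requires_grad, (x,), vjp)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    mask = (x.data > lo) & (x.data < hi)

    def vjp(g):
        return ((x, g * mask),)

    return Tensor(np.clip(x.data, lo, hi), x.requires_grad, (x,), vjp)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def vjp(g):
        return ((x, np.full_like(x.data, float(g) / n)),)

    return Tensor(x.data.mean(), x.requires_grad, (x,), vjp)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        pieces = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pieces.append((t, g[tuple(sl)]))
        return tuple(pieces)

    rg = any(t.requires_grad for t in tensors)
    return Tensor(out_data, rg, tuple(tensors), vjp)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def vjp(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        return ((x, full),)

    return Tensor(x.data[sl], x.requires_grad, (x,), vjp)


# ---------------------------------------------------------------------------
# reductions used by attention blocks
# ---------------------------------------------------------------------------

def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis of a (B, C, H, W) map, keepdims."""
    idx = x.data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(x.data, idx, axis=1)

    def vjp(g):
        full = np.zeros_like(x.data)
        np.put_along_axis(full, idx, g, axis=1)
        return ((x, full),)

    return Tensor(out_data, x.requires_grad, (x,), vjp)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]

    def vjp(g):
        return ((x, np.repeat(g / c, c, axis=1)),)

    return Tensor(x.data.mean(axis=1, keepdims=True), x.requires_grad, (x,), vjp)


def spatial_max(x: Tensor) -> Tensor:
    """Global max pooling of a (B, C, H, W) map to (B, C, 1, 1)."""
    b, c, h, w = x.data.shape
    flat = x.data.reshape(b, c, -1)
    idx = flat.argmax(axis=2, keepdims=True)
    out_data = np.take_along_axis(flat, idx, axis=2).reshape(b, c, 1, 1)

    def vjp(g):
        full = np.zeros_like(flat)
        np.put_along_axis(full, idx, g.reshape(b, c, 1), axis=2)
        return ((x, full.reshape(x.data.shape)),)

    return Tensor(out_data, x.requires_grad, (x,), vjp)


def spatial_mean(x: Tensor) -> Tensor:
    b, c, h, w = x.data.shape
    n = h * w

    def vjp(g):
        return ((x, np.broadcast_to(g / n, x.data.shape).copy()),)

    return Tensor(x.data.mean(axis=(2, 3), keepdims=True), x.requires_grad, (x,), vjp)


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=4)
    out_data = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]

    def vjp(g):
        gfull = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(gfull, idx[..., None], g[..., None], axis=4)
        gfull = gfull.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return ((x, gfull.reshape(b, c, h, w)),)

    return Tensor(out_data, x.requires_grad, (x,), vjp)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int, dilation: int = 1) -> Tensor:
    """3x3-style cross-correlation, stride 1, square kernel.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,) or None.
    """
    bsz, cin, h, wd = x.data.shape
    cout, cin_w, k, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    span = dilation * (k - 1) + 1
    ho = h + 2 * padding - span + 1
    wo = wd + 2 * padding - span + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("conv2d output would be empty; increase padding")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_data = np.zeros((bsz, cout, ho, wo))
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i * dilation : i * dilation + ho, j * dilation : j * dilation + wo]
            out_data += np.einsum("oc,bchw->bohw", w.data[:, :, i, j], patch, optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def vjp(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i * dilation : i * dilation + ho, j * dilation : j * dilation + wo]
                gw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                gxp[:, :, i * dilation : i * dilation + ho, j * dilation : j * dilation + wo] += np.einsum(
                    "oc,bohw->bchw", w.data[:, :, i, j], g, optimize=True
                )
        gx = gxp[:, :, padding : padding + h, padding : padding + wd] if padding else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    rg = any(p.requires_grad for p in parents)
    return Tensor(out_data, rg, parents, vjp)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int, output_padding: int
) -> Tensor:
    """Transposed convolution (fractionally-strided), square kernel.

    x: (B, Cin, H, W); w: (Cin, Cout, k, k). Output spatial size is
    (H-1)*stride - 2*padding + k + output_padding.
    """
    bsz, cin, h, wd = x.data.shape
    cin_w, cout, k, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: input {cin}, weight {cin_w}")
    hf = (h - 1) * stride + k
    wf = (wd - 1) * stride + k
    ho = hf - 2 * padding + output_padding
    wo = wf - 2 * padding + output_padding
    full = np.zeros((bsz, cout, hf + output_padding, wf + output_padding))
    for i in range(k):
        for j in range(k):
            full[:, :, i : i + stride * (h - 1) + 1 : stride, j : j + stride * (wd - 1) + 1 : stride] += np.einsum(
                "co,bchw->bohw", w.data[:, :, i, j], x.data, optimize=True
            )
    out_data = full[:, :, padding : padding + ho, padding : padding + wo]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def vjp(g):
        gfull = np.zeros_like(full)
        gfull[:, :, padding : padding + ho, padding : padding + wo] = g
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for i in range(k):
            for j in range(k):
                sl = gfull[:, :, i : i + stride * (h - 1) + 1 : stride, j : j + stride * (wd - 1) + 1 : stride]
                gx += np.einsum("co,bohw->bchw", w.data[:, :, i, j], sl, optimize=True)
                gw[:, :, i, j] = np.einsum("bchw,bohw->co", x.data, sl, optimize=True)
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    rg = any(p.requires_grad for p in parents)
    return Tensor(out_data, rg, parents, vjp)


def conv1d_channels(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """1-D cross-channel convolution of a (B, C, 1, 1) descriptor.

    Shared kernel ``w`` of odd length slides across the channel axis with
    zero padding, as in efficient channel attention.
    """
    bsz, c = x.data.shape[:2]
    k = w.data.shape[0]
    pad = k // 2
    flat = x.data.reshape(bsz, c)
    fp = np.pad(flat, ((0, 0), (pad, pad)))
    out = np.zeros((bsz, c))
    for i in range(k):
        out += w.data[i] * fp[:, i : i + c]
    if b is not None:
        out = out + b.data

    def vjp(g):
        g2 = g.reshape(bsz, c)
        gw = np.array([(g2 * fp[:, i : i + c]).sum() for i in range(k)])
        gfp = np.zeros_like(fp)
        for i in range(k):
            gfp[:, i : i + c] += w.data[i] * g2
        gx = gfp[:, pad : pad + c].reshape(x.data.shape)
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, np.array([g2.sum()])))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    rg = any(p.requires_grad for p in parents)
    return Tensor(out.reshape(x.data.shape), rg, parents, vjp)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over (B, H, W) per channel.

    In training mode the batch statistics are used (and the running buffers
    updated in place); gradients flow through the statistics. In eval mode
    the running buffers act as constants.
    """
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def vjp(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        scale = (gamma.data * inv)[None, :, None, None]
        if training:
            gm = g.mean(axis=(0, 2, 3))[None, :, None, None]
            gxh = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
            gx = scale * (g - gm - xhat * gxh)
        else:
            gx = scale * g
        return ((x, gx), (gamma, ggamma), (beta, gbeta))

    rg = x.requires_grad or gamma.requires_grad or beta.requires_grad
    return Tensor(out_data, rg, (x, gamma, beta), vjp)
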