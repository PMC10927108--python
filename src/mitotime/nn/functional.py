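"""Differentiable operations for the conv-net engine.

Convolutions are im2col/matmul based so the heavy lifting happens inside
BLAS.  All spatial operators use NCHW layout; convolution weights are
``(out_channels, in_channels, k, k)`` and transpose-convolution weights are
``(in_channels, out_channels, k, k)``.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "select",
    "relu",
    "sigmoid",
    "tanh",
    "log",
    "clamp",
    "linear",
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "batch_norm2d",
    "upsample_bilinear_2x",
    "stack",
    "binary_cross_entropy",
]


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data * out_data))

    return Tensor._make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.log(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor._make(out_data, (x,), backward)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient passes only through the interior."""
    x = as_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    interior = (x.data > lo) & (x.data < hi)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * interior)

    return Tensor._make(out_data, (x,), backward)


def binary_cross_entropy(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Elementwise BCE with the probability clamped to [eps, 1-eps].

    Returns a tensor of the same shape as ``pred``; reduce with ``.mean()``
    to obtain the conventions of the individual loss definitions.
    """
    pred = as_tensor(pred)
    t = np.asarray(target, dtype=pred.data.dtype)
    if t.shape != pred.shape:
        raise ValueError(f"target shape {t.shape} != prediction shape {pred.shape}")
    p = np.clip(pred.data, eps, 1.0 - eps)
    out_data = -(t * np.log(p) + (1.0 - t) * np.log1p(-p))
    interior = (pred.data > eps) & (pred.data < 1.0 - eps)

    def backward(g):
        if pred.requires_grad:
            pred._accumulate(g * interior * (p - t) / (p * (1.0 - p)))

    return Tensor._make(out_data, (pred,), backward)


# ---------------------------------------------------------------------------
# dense
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, D) @ w.T (D, M) + b."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            w._accumulate(g.T @ x.data)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# convolution plumbing (shared by conv2d / conv_transpose2d)
# ---------------------------------------------------------------------------

def _pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    if not pad:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    out[:, :, pad:-pad, pad:-pad] = x
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> columns (N, C*k*k, Ho*Wo), plus output spatial dims."""
    n, c, h, w = x.shape
    x = _pad2d(x, pad)
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    if k == 1 and stride == 1:
        return x.reshape(n, c, ho * wo), ho, wo
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        hi = i + stride * ho
        for j in range(k):
            wj = j + stride * wo
            cols[:, :, i, j] = x[:, :, i:hi:stride, j:wj:stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add columns (N, C*k*k, Ho*Wo) back onto an (N, C, H, W) image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        hi = i + stride * ho
        for j in range(k):
            wj = j + stride * wo
            out[:, :, i:hi:stride, j:wj:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    n = x.shape[0]
    f, c, k, _ = w.shape
    cols, ho, wo = _im2col(x, k, stride, pad)
    y = np.matmul(w.reshape(f, c * k * k)[None], cols)
    return y.reshape(n, f, ho, wo), cols


def _conv_backward_input(gy: np.ndarray, w: np.ndarray, x_shape, stride: int, pad: int):
    n = gy.shape[0]
    f, c, k, _ = w.shape
    gy2 = gy.reshape(n, f, -1)
    gcols = np.matmul(w.reshape(f, c * k * k).T[None], gy2)
    return _col2im(gcols, x_shape, k, stride, pad)


def _conv_backward_weight(gy: np.ndarray, cols: np.ndarray, w_shape):
    f, c, k, _ = w_shape
    n = gy.shape[0]
    gy2 = gy.reshape(n, f, -1)
    gw = np.einsum("nfl,ncl->fc", gy2, cols, optimize=True)
    return gw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW."""
    x, w = as_tensor(x), as_tensor(w)
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects 4-D input and weight")
    if x.shape[1] != w.shape[1]:
        raise ValueError(
            f"input channels {x.shape[1]} != weight in-channels {w.shape[1]}")
    out_data, cols = _conv_forward(x.data, w.data, stride, padding)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            x._accumulate(_conv_backward_input(g, w.data, x.shape, stride, padding))
        if w.requires_grad:
            w._accumulate(_conv_backward_weight(g, cols, w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transpose convolution; weight is (C_in, C_out, k, k).

    With the defaults (k=3, stride=2, padding=1, output_padding=1) spatial
    dimensions double exactly.
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, cout, k, _ = w.shape
    if x.shape[1] != cin:
        raise ValueError(f"input channels {x.shape[1]} != weight in-channels {cin}")
    n, _, h, win = x.shape
    ho = (h - 1) * stride - 2 * padding + k + output_padding
    wo = (win - 1) * stride - 2 * padding + k + output_padding
    # forward pass == input-gradient of a conv mapping (ho, wo) -> (h, w),
    # whose weight (filters=Cin over Cout channels) is exactly w's layout
    wc = np.ascontiguousarray(w.data)
    out_data = _conv_backward_input(x.data, wc, (n, cout, ho, wo), stride, padding)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        if x.requires_grad:
            gx, _ = _conv_forward(g, wc, stride, padding)
            x._accumulate(gx)
        if w.requires_grad:
            cols, _, _ = _im2col(g, k, stride, padding)
            w._accumulate(_conv_backward_weight(x.data, cols, wc.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling / normalization / resize
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling with stride k (spatial dims must be divisible by k)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = xr.max(axis=(3, 5))
    mask = xr == out_data[:, :, :, None, :, None]

    def backward(g):
        if x.requires_grad:
            gexp = mask * g[:, :, :, None, :, None]
            x._accumulate(gexp.reshape(n, c, h, w))

    return Tensor._make(out_data, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean``/``running_var`` are updated in place in training mode.
    """
    x = as_tensor(x)
    n, c, h, w = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = n * h * w

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxhat = g * gamma.data[None, :, None, None]
        if training:
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None]
        else:
            gx = gxhat * inv_std[None, :, None, None]
        x._accumulate(gx)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Double one axis with the separable [1,3,3,1]/4 stride-2 kernel
    (zero-padded borders, align_corners=False convention)."""
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    even, odd = out[..., 0::2], out[..., 1::2]
    even[...] = 0.75 * x
    even[..., 1:] += 0.25 * x[..., :-1]
    odd[...] = 0.75 * x
    odd[..., :-1] += 0.25 * x[..., 1:]
    return np.moveaxis(out, -1, axis)


def _up1d_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up1d` (used in the backward pass)."""
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    gx = 0.75 * (ge + go)
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 1:] += 0.25 * go[..., :-1]
    return np.moveaxis(gx, -1, axis)


def upsample_bilinear_2x(x: Tensor) -> Tensor:
    """Fixed (non-learned) bilinear x2 upsampling of NCHW maps.

    Equivalent to a per-channel transpose convolution with the classic
    separable [1, 3, 3, 1]/4 kernel (stride 2, padding 1).
    """
    x = as_tensor(x)
    out_data = _up1d(_up1d(x.data, 2), 3)

    def backward(g):
        if x.requires_grad:
            x._accumulate(_up1d_T(_up1d_T(g, 3), 2))

    return Tensor._make(out_data, (x,), backward)


def select(x: Tensor, index: int, axis: int = 0) -> Tensor:
    """Index one slice along ``axis`` (removing that axis)."""
    x = as_tensor(x)
    sl = [slice(None)] * x.ndim
    sl[axis] = index
    sl = tuple(sl)
    out_data = x.data[sl]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[sl] = g
            x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(np.squeeze(piece, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
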