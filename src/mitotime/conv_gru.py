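"""Convolutional gated recurrent units.

A ConvGRU carries a hidden feature map across the frames of one time-lapse
sequence at a fixed spatial resolution: the usual GRU gate equations with
every matrix product replaced by a same-padded 2-D convolution, so the
spatial dimensions of the features are never changed.  Gates follow the
Cho-style formulation

    z = sigmoid(W_xz * x + W_hz * h + b_z)          (update gate)
    r = sigmoid(W_xr * x + W_hr * h + b_r)          (reset gate)
    h~ = tanh(W_xh * x + W_hh * (r . h) + b_h)      (candidate)
    h' = (1 - z) . h + z . h~

with ``*`` a convolution and ``.`` the elementwise product.  The hidden
state is initialized to zeros at every sequence start, which makes the
all-zero-parameter unit an exact halving map (z = 1/2, h~ = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor

__all__ = ["ConvGRUSpec", "ConvGRUState", "ConvGRU", "gru_step", "gru_run",
           "gru_run_batched"]


@dataclass(frozen=True)
class ConvGRUSpec:
    """Shape contract of one ConvGRU layer.

    Input and hidden channel counts are equal (the unit sits at the output
    of a backbone stage whose width it matches), and same-padding keeps the
    spatial dimensions fixed.
    """

    channels: int
    kernel: int = 3

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")

    @property
    def padding(self) -> int:
        return self.kernel // 2


@dataclass
class ConvGRUState:
    """Hidden feature map (channels, height, width) — or batched 4-D."""

    h: Tensor

    @classmethod
    def zeros(cls, channels: int, height: int, width: int,
              batch: int | None = None, dtype=np.float32) -> "ConvGRUState":
        shape = (channels, height, width) if batch is None else (batch, channels, height, width)
        return cls(Tensor(np.zeros(shape, dtype=dtype)))


class ConvGRU(nn.Module):
    """One convolutional GRU layer; holds the six gate convolutions.

    Input-to-hidden convolutions carry the gate bias, hidden-to-hidden
    convolutions are bias-free, so each gate has exactly one bias term.
    """

    def __init__(self, spec: ConvGRUSpec, *, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c, k, p = spec.channels, spec.kernel, spec.padding
        # gain 1 (Xavier-like): gate pre-activations should start small so
        # the unit opens near the z = 1/2 fixed point
        def conv(bias):
            return nn.Conv2d(c, c, k, padding=p, bias=bias, rng=rng, gain=1.0)

        self.wxz, self.whz = conv(True), conv(False)
        self.wxr, self.whr = conv(True), conv(False)
        self.wxh, self.whh = conv(True), conv(False)

    def step(self, x, h_prev):
        return gru_step(self, x, h_prev)

    def run(self, xs, h0=None):
        return gru_run(self, xs, h0)


def _as_state(h) -> ConvGRUState:
    if isinstance(h, ConvGRUState):
        return h
    return ConvGRUState(as_tensor(h))


def gru_step(params: ConvGRU, x, h_prev) -> ConvGRUState:
    """One recurrent update; output spatial dims equal input spatial dims."""
    x = as_tensor(x)
    h = _as_state(h_prev).h
    squeeze = x.ndim == 3
    if squeeze:  # allow unbatched (C, H, W) maps
        x = x.reshape(1, *x.shape)
        h = h.reshape(1, *h.shape)
    if x.shape != h.shape:
        raise ValueError(f"input shape {x.shape} != hidden shape {h.shape}")
    if x.shape[1] != params.spec.channels:
        raise ValueError(
            f"expected {params.spec.channels} channels, got {x.shape[1]}")
    z = F.sigmoid(params.wxz(x) + params.whz(h))
    r = F.sigmoid(params.wxr(x) + params.whr(h))
    h_cand = F.tanh(params.wxh(x) + params.whh(r * h))
    h_new = (1.0 - z) * h + z * h_cand
    if squeeze:
        h_new = h_new.reshape(*h_new.shape[1:])
    return ConvGRUState(h_new)


def gru_run(params: ConvGRU, xs, h0=None) -> list[ConvGRUState]:
    """Apply :func:`gru_step` along a sequence of feature maps.

    The initial state defaults to zeros; it is always explicit in the sense
    that state is never carried over from a previous call, which enforces
    the sequence-boundary contract.
    """
    xs = [as_tensor(x) for x in xs]
    if len(xs) == 0:
        raise ValueError("empty sequence")
    first = xs[0]
    if h0 is None:
        h = ConvGRUState(Tensor(np.zeros(first.shape, dtype=first.data.dtype)))
    else:
        h = _as_state(h0)
    states = []
    for x in xs:
        if x.shape != first.shape:
            raise ValueError("all feature maps in a sequence must share a shape")
        h = gru_step(params, x, h)
        states.append(h)
    return states


def gru_run_batched(params: ConvGRU, xs: Tensor, h0: Tensor | None = None) -> Tensor:
    """Run the GRU over a (B, T, C, H, W) tensor of feature maps.

    Algebraically identical to iterating :func:`gru_step` over t (checked
    by a unit test), but the three input-to-hidden convolutions — which do
    not depend on the recurrence — are applied to all frames in one batched
    call, leaving only the hidden-to-hidden convolutions inside the time
    loop.  Returns the stacked hidden states as a (B, T, C, H, W) tensor.
    The initial state defaults to zeros, so state never leaks between
    sequences.
    """
    b, t, c, hh, ww = xs.shape
    flat = xs.reshape(b * t, c, hh, ww)
    xz = params.wxz(flat).reshape(b, t, c, hh, ww)
    xr = params.wxr(flat).reshape(b, t, c, hh, ww)
    xh = params.wxh(flat).reshape(b, t, c, hh, ww)
    if h0 is None:
        h = Tensor(np.zeros((b, c, hh, ww), dtype=xs.data.dtype))
    else:
        h = _as_state(h0).h
    out = []
    for i in range(t):
        z = F.sigmoid(F.select(xz, i, 1) + params.whz(h))
        r = F.sigmoid(F.select(xr, i, 1) + params.whr(h))
        h_cand = F.tanh(F.select(xh, i, 1) + params.whh(r * h))
        h = (1.0 - z) * h + z * h_cand
        out.append(h)
    return F.stack(out, axis=1)
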