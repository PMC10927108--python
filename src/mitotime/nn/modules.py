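"""Layer abstractions over the autograd engine.

Modules own :class:`Parameter` tensors and optional buffers (batch-norm
running statistics).  Parameter initialization is He-style and driven by an
explicit ``numpy.random.Generator`` so model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "Sequential",
    "SGD",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Minimal torch-like module: parameter registry + train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data = np.asarray(arr, dtype=DTYPE)
            else:
                buffers[name][...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int, gain: float = 2.0):
    std = np.sqrt(gain / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator, gain: float = 2.0):
        super().__init__()
        fan_in = cin * kernel * kernel
        self.weight = Parameter(_he_normal(rng, (cout, cin, kernel, kernel), fan_in, gain))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 2,
                 padding: int = 1, output_padding: int = 1, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        # with stride-s zero-stuffing only ~k^2/s^2 taps see a nonzero
        # input, so the effective fan-in is smaller by s^2
        fan_in = max(cin * kernel * kernel // (stride * stride), 1)
        self.weight = Parameter(_he_normal(rng, (cin, cout, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class Linear(Module):
    def __init__(self, din: int, dout: int, bias: bool = True, *,
                 rng: np.random.Generator, gain: float = 2.0):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (dout, din), din, gain))
        self.bias = Parameter(np.zeros(dout)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.momentum,
                              self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return F.max_pool2d(x, self.k)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
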