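"""Parameterised layers on top of the autograd core.

Follows the familiar module convention: each layer owns named parameter
tensors, ``forward`` takes a Tensor (or ndarray) plus a ``training`` flag,
and ``named_parameters()`` walks the tree so optimizers and checkpoints can
address every trainable scalar by a stable dotted path.
"""

from __future__ import annotations

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for cname, child in self._children():
            yield from child.named_parameters(f"{prefix}{cname}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in params.items():
            p.data[...] = state[name]
        for name, buf in buffers.items():
            buf[...] = state[name]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for cname, child in self._children():
            yield from child.named_buffers(f"{prefix}{cname}.")

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x, training: bool = False, **kw):
        return self.forward(ag.as_tensor(x), training=training, **kw)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, padding=0, dilation=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        self.weight = Tensor(_he_normal(rng, (cout, cin, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.padding = padding
        self.dilation = dilation

    def forward(self, x, training=False):
        if x.ndim != 4:
            raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
        return ag.conv2d(x, self.weight, self.bias, self.padding, self.dilation)


class ConvTranspose2d(Module):
    """Kernel-3 stride-2 transposed conv doubles spatial dims exactly
    (padding 1, output_padding 1)."""

    def __init__(self, cin, cout, kernel=3, stride=2, padding=1, output_padding=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            _he_normal(rng, (cin, cout, kernel, kernel), cin * kernel * kernel), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding

    def forward(self, x, training=False):
        return ag.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding, self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        return ag.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training, self.momentum, self.eps,
        )


class Conv1dChannels(Module):
    """Shared odd-length kernel sliding across the channel axis of a
    (B, C, 1, 1) descriptor, zero-padded so C is preserved."""

    def __init__(self, kernel=3, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        if kernel % 2 == 0:
            raise ValueError(f"cross-channel kernel must be odd, got {kernel}")
        self.weight = Tensor(rng.normal(0.0, np.sqrt(1.0 / kernel), kernel), requires_grad=True)
        self.bias = Tensor(np.zeros(1), requires_grad=True) if bias else None

    def forward(self, x, training=False):
        return ag.conv1d_channels(x, self.weight, self.bias)
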