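"""Layer abstractions over the functional ops (a torch.nn-like surface)."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

DTYPE = np.float64


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=DTYPE).reshape(params[name].shape)
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unexpected state entry {name!r}")


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 'same' convolution; supports dilation and depthwise groups."""

    def __init__(self, in_ch, out_ch, kernel_size, dilation=1, groups=1,
                 bias=True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        kh, kw = kernel_size
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dilation, self.groups = dilation, groups
        fan_in = (in_ch // groups) * kh * kw
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias,
                        dilation=self.dilation, groups=self.groups)


class UpConv2x2(Module):
    """Transposed 2x2 stride-2 convolution (learned x2 upsampling)."""

    def __init__(self, in_ch, out_ch, bias=True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.up_conv2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch, dtype=DTYPE)
        self.running_var = np.ones(num_ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training,
                            momentum=self.momentum, eps=self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng()

    def forward(self, x):
        return F.dropout(x, self.p, self.rng, self.training)


class MaxPool2x2(Module):
    def forward(self, x):
        return F.max_pool2x2(x)


class AvgPool(Module):
    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        return F.avg_pool(x, self.factor)
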