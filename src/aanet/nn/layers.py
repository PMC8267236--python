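"""Layer abstractions over the autodiff engine: Module, Conv2d, BatchNorm2d."""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor (always requires_grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal container with recursive parameter/buffer traversal."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
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
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
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

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {own[name].data.shape} vs {arr.shape}")
                own[name].data = arr.astype(own[name].data.dtype).copy()
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)}")


class Conv2d(Module):
    """Stride-1 2-D convolution with He-normal weight initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, padding=self.padding,
                        dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = T.batchnorm2d(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (
                mean.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (
                var.astype(np.float32) - self.running_var)
            return out
        out, _, _ = T.batchnorm2d(x, self.gamma, self.beta, self.eps,
                                  mean=self.running_mean.astype(x.data.dtype),
                                  var=self.running_var.astype(x.data.dtype))
        return out


class ConvBNReLU(Module):
    """The recurring conv -> batchnorm -> ReLU unit."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size,
                           padding=padding, dilation=dilation, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))
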