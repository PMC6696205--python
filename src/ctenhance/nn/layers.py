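"""Layer/module abstraction over the autograd primitives.

Modules own parameters (Tensors with ``requires_grad=True``) and
non-trainable buffers (running batch-norm statistics). ``state_dict``
flattens both into name -> ndarray for single-file checkpoints.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- discovery -----------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- train / eval --------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                target = params[name]
                if target.data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {target.data.shape} vs {value.shape}"
                    )
                target.data = np.asarray(value, dtype=DTYPE)
            elif kind == "buffer":
                buffers[name][...] = value
            else:  # pragma: no cover
                raise ValueError(f"bad state key {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding by default."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, padding="same"):
        super().__init__()
        if in_channels < 1 or out_channels < 1 or kernel_size < 1:
            raise ValueError("channel counts and kernel size must be >= 1")
        k = int(kernel_size)
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel_size = k
        self.padding = (k - 1) // 2 if padding == "same" else int(padding)
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ConvBNReLU(Module):
    """conv -> batch-norm -> rectifier, the stem/block unit of the classifier."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, use_bn=True):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.bn = BatchNorm2d(out_channels) if use_bn else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return ag.relu(y)
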