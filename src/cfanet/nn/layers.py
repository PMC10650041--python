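"""Layer/module abstractions over the autograd kernels."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .autograd import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "BatchNorm2d", "ReLU", "ConvBNReLU",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._parameters: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True) -> "Module":
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        """Total number of trainable scalar parameters."""
        return sum(p.data.size for p in self.parameters())

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> list[str]:
        """Load a flat name->array mapping; returns the list of skipped keys."""
        own_params = dict(self.named_parameters())
        own_buffers = dict(self.named_buffers())
        skipped = []
        for name, value in state.items():
            value = np.asarray(value)
            if name in own_params:
                target = own_params[name]
                if target.data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for '{name}': "
                        f"expected {target.data.shape}, got {value.shape}"
                    )
                target.data = value.astype(np.float32)
            elif name in own_buffers:
                buf = own_buffers[name]
                if buf.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for buffer '{name}': "
                        f"expected {buf.shape}, got {value.shape}"
                    )
                buf[...] = value
            else:
                skipped.append(name)
        if strict:
            missing = (set(own_params) | set(own_buffers)) - set(state)
            if missing:
                raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        return skipped

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, mod in enumerate(mods):
            setattr(self, str(i), mod)
        self._order = [str(i) for i in range(len(mods))]

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]

    def forward(self, x: Tensor) -> Tensor:
        for key in self._order:
            x = self._modules[key](x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._order: list[str] = []
        for mod in mods:
            self.append(mod)

    def append(self, mod: Module) -> None:
        key = str(len(self._order))
        setattr(self, key, mod)
        self._order.append(key)

    def __iter__(self):
        return (self._modules[k] for k in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i):
        return self._modules[self._order[i]]


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    """2-D convolution with Kaiming-uniform initialization (fan-in, ReLU gain)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        padding_mode: str = "zeros",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.padding_mode = padding_mode
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = Parameter(
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel_size, kernel_size))
        )
        if bias:
            bbound = float(1.0 / np.sqrt(fan_in))
            self.bias = Parameter(rng.uniform(-bbound, bbound, out_channels))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, padding_mode=self.padding_mode)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(
            x, self.weight, self.bias,
            self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


def ConvBNReLU(
    in_channels: int,
    out_channels: int,
    kernel_size: int,
    stride: int = 1,
    padding: int | None = None,
    padding_mode: str = "zeros",
    rng: np.random.Generator | None = None,
) -> Sequential:
    """conv (no bias) -> batch norm -> ReLU, the default fusion/decoder unit."""
    if padding is None:
        padding = kernel_size // 2
    return Sequential(
        Conv2d(in_channels, out_channels, kernel_size, stride=stride,
               padding=padding, bias=False, padding_mode=padding_mode, rng=rng),
        BatchNorm2d(out_channels),
        ReLU(),
    )
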