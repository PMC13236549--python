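"""Layer primitives built on the autograd tensor.

Parameters are float32; initialisation is deterministic given the generator
passed to each constructor, so whole networks are reproducible from one seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv3d, conv_transpose3d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


class Module:
    """Minimal parameter container with recursive traversal."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module | Parameter"]]:
        for name, val in vars(self).items():
            if isinstance(val, (Parameter, Module)):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in self._children():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            else:
                yield from val.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng=0, scale: float | None = None):
        r = _rng(rng)
        std = scale if scale is not None else np.sqrt(2.0 / in_features)
        self.weight = Parameter(r.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (v + self.eps).sqrt() * self.gamma + self.beta


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True, rng=0):
        r = _rng(rng)
        k = kernel_size
        fan_in = in_channels * k**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(r.normal(0.0, std, size=(out_channels, in_channels, k, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """Transposed convolution with kernel == stride (pure upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, factor: int,
                 bias: bool = True, rng=0):
        r = _rng(rng)
        fan_in = in_channels
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            r.normal(0.0, std, size=(in_channels, out_channels, factor, factor, factor)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, factor=self.factor)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        return xc / (v + self.eps).sqrt() * self.gamma + self.beta
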