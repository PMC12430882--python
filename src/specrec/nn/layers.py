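"""Minimal layer/module abstractions over the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Sequential", "Identity",
           "n_parameters"]


class Module:
    """Base class: recursive parameter discovery and checkpoint dicts."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def n_parameters(module: Module) -> int:
    """Total number of trainable scalars in a module."""
    return sum(p.data.size for p in module.parameters())


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype=np.float64) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """2-D convolution; ``padding`` defaults to 'same' for stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64,
                 init_scale: float = 1.0):
        rng = np.random.default_rng() if rng is None else rng
        if padding is None:
            padding = kernel_size // 2 if stride == 1 else 0
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            init_scale
            * _he_init(rng, (out_channels, in_channels, kernel_size, kernel_size),
                       fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
            if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution; default 2×2 kernel with stride 2 (exact ×2)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 stride: int = 2, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = np.random.default_rng() if rng is None else rng
        self.stride = stride
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(
            _he_init(rng, (in_channels, out_channels, kernel_size, kernel_size),
                     fan_in, dtype),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
            if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for module in self.modules:
            x = module(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
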