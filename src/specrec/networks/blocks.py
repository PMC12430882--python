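"""Shared building blocks: attention gates, local–global fusion, residual units.

All gating modules act multiplicatively with sigmoid-bounded weights in (0, 1).
The channel-statistic gates (dual-stat and channel attention) apply a small
two-layer bottleneck *per channel with shared weights*, so they are equivariant
under channel permutation: identical channels always receive identical gates.
"""

from __future__ import annotations

import numpy as np

from ..nn import Conv2d, Module, Tensor, concat

__all__ = ["DualStatGate", "ChannelGate", "SpatialGate", "LGFBlock", "LBlock"]

_STD_EPS = 1e-8


class DualStatGate(Module):
    """Dual-statistic channel gate for skip-connection features.

    Each channel's spatial mean and standard deviation are passed through a
    shared two-layer bottleneck ending in a sigmoid; the resulting per-channel
    gate in (0, 1) scales the channel.  Constant channels (zero std) are
    well-defined via a small variance floor.
    """

    def __init__(self, hidden: int = 8, rng=None, dtype=np.float64):
        self.fc1 = Conv2d(2, hidden, 1, rng=rng, dtype=dtype)
        self.fc2 = Conv2d(hidden, 1, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n, c, _, _ = x.shape
        mu = x.mean(axis=(2, 3), keepdims=True)  # (N,C,1,1)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        sd = (var + _STD_EPS).sqrt()
        stats = concat([mu.reshape(n, 1, c, 1), sd.reshape(n, 1, c, 1)], axis=1)
        gate = self.fc2(self.fc1(stats).relu()).sigmoid()  # (N,1,C,1)
        return x * gate.reshape(n, c, 1, 1)


class ChannelGate(Module):
    """Channel attention: gate each channel from its global average, through a
    shared per-channel bottleneck with sigmoid output."""

    def __init__(self, hidden: int = 8, rng=None, dtype=np.float64):
        self.fc1 = Conv2d(1, hidden, 1, rng=rng, dtype=dtype)
        self.fc2 = Conv2d(hidden, 1, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        n, c, _, _ = x.shape
        mu = x.mean(axis=(2, 3), keepdims=True).reshape(n, 1, c, 1)
        gate = self.fc2(self.fc1(mu).relu()).sigmoid()
        return x * gate.reshape(n, c, 1, 1)


class SpatialGate(Module):
    """Spatial attention: per-pixel gate from the channel-mean and channel-max
    maps through a 3×3 convolution and sigmoid."""

    def __init__(self, rng=None, dtype=np.float64):
        self.conv = Conv2d(2, 1, 3, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        pooled = concat([x.mean(axis=1, keepdims=True),
                         x.max(axis=1, keepdims=True)], axis=1)
        gate = self.conv(pooled).sigmoid()  # (N,1,H,W)
        return x * gate


class LGFBlock(Module):
    """Local–global fusion block, residual form.

    A 3×3 convolutional local path and a globally average-pooled context
    vector (broadcast back over the image) are concatenated and fused by a
    1×1 convolution; the fused update is added to the input.  The fusion
    convolution is zero-initialised, so at initialisation the block is exactly
    the identity — the residual update is learned from nothing, which keeps
    deep unnormalised stacks stable.
    """

    def __init__(self, channels: int, rng=None, dtype=np.float64):
        self.local = Conv2d(channels, channels, 3, rng=rng, dtype=dtype)
        self.context = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.fuse = Conv2d(2 * channels, channels, 1, rng=rng, dtype=dtype,
                           init_scale=0.0)

    def forward(self, x: Tensor) -> Tensor:
        local = self.local(x).relu()
        ctx = self.context(x.mean(axis=(2, 3), keepdims=True)).relu()
        ctx = ctx.broadcast_to(x.shape)
        return x + self.fuse(concat([local, ctx], axis=1))


class LBlock(Module):
    """Residual attention unit: projected shortcut plus a conv–attention path.

    ``out = shortcut(x) + SA(CA(conv3×3(relu(conv3×3(x)))))`` with the
    shortcut a learned 1×1 linear transform of the input.  The second
    convolution of the attention path is zero-initialised so the unit starts
    as its linear shortcut (stable deep stacking without normalisation).
    """

    def __init__(self, channels: int, rng=None, dtype=np.float64):
        self.shortcut = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.conv1 = Conv2d(channels, channels, 3, rng=rng, dtype=dtype)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng, dtype=dtype,
                            init_scale=0.0)
        self.ca = ChannelGate(rng=rng, dtype=dtype)
        self.sa = SpatialGate(rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        path = self.conv2(self.conv1(x).relu())
        path = self.sa(self.ca(path))
        return self.shortcut(x) + path
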