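"""The sample branch: a U-Net-like spectral upsampler from RGB to a radiance cube.

An encoder of local–global fusion (LGF) stages with strided-convolution
downsampling, an LGF bottleneck, and a transposed-convolution decoder whose
skip connections pass encoder features through dual-stat attention gates.
The final 3×3 head is added to the input lifted from 3 to B channels by a
fixed 1×1 tiling projection, keeping the global residual well-typed across
the channel-count change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..nn import (Conv2d, ConvTranspose2d, Identity, Module, Sequential,
                  Tensor, concat, conv2d)
from .blocks import DualStatGate, LGFBlock

__all__ = ["RadianceNetConfig", "RadianceUNet"]


@dataclass(frozen=True)
class RadianceNetConfig:
    """Architecture hyperparameters of the sample branch."""

    in_channels: int = 3
    out_channels: int = 32  # working band count B
    base_width: int = 32
    n_stages: int = 3
    lgf_counts: tuple[int, int, int] = (2, 2, 2)  # encoder, bottleneck, decoder
    use_dsa: bool = True
    use_lgf: bool = True  # plain 3×3 convolutions when disabled (ablation)

    def __post_init__(self) -> None:
        if self.n_stages < 1 or self.base_width < 1:
            raise ValueError("n_stages and base_width must be ≥ 1")
        if len(self.lgf_counts) != 3 or any(k < 1 for k in self.lgf_counts):
            raise ValueError("lgf_counts must be three positive ints")


def _feature_stack(channels: int, count: int, use_lgf: bool, rng, dtype) -> Sequential:
    if use_lgf:
        return Sequential(*[LGFBlock(channels, rng=rng, dtype=dtype)
                            for _ in range(count)])
    return Sequential(*[Conv2d(channels, channels, 3, rng=rng, dtype=dtype)
                        for _ in range(count)])


class RadianceUNet(Module):
    """Maps a batch of RGB images (N,3,H,W) to radiance cubes (N,B,H,W)."""

    def __init__(self, cfg: RadianceNetConfig, seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        k1, k2, k3 = cfg.lgf_counts
        widths = [cfg.base_width * 2**i for i in range(cfg.n_stages + 1)]

        self.stem = Conv2d(cfg.in_channels, widths[0], 3, rng=rng, dtype=dtype)
        self.enc_stacks = [
            _feature_stack(widths[i], k1, cfg.use_lgf, rng, dtype)
            for i in range(cfg.n_stages)
        ]
        self.downs = [
            Conv2d(widths[i], widths[i + 1], 3, stride=2, padding=1,
                   rng=rng, dtype=dtype)
            for i in range(cfg.n_stages)
        ]
        self.bottleneck = _feature_stack(widths[-1], k2, cfg.use_lgf, rng, dtype)
        self.ups = [
            ConvTranspose2d(widths[i + 1], widths[i], rng=rng, dtype=dtype)
            for i in reversed(range(cfg.n_stages))
        ]
        self.skip_gates = [
            DualStatGate(rng=rng, dtype=dtype) if cfg.use_dsa else Identity()
            for _ in range(cfg.n_stages)
        ]
        self.merges = [
            Conv2d(2 * widths[i], widths[i], 1, rng=rng, dtype=dtype)
            for i in reversed(range(cfg.n_stages))
        ]
        self.dec_stacks = [
            _feature_stack(widths[i], k3, cfg.use_lgf, rng, dtype)
            for i in reversed(range(cfg.n_stages))
        ]
        # small head init: at initialisation the output is dominated by the
        # lifted-RGB residual, a physically sensible starting radiance
        self.head = Conv2d(widths[0], cfg.out_channels, 3, rng=rng, dtype=dtype,
                           init_scale=0.1)
        # fixed channel-lifting projection for the global residual: tiles the
        # RGB input across the B output bands; not trained
        lift = np.zeros((cfg.out_channels, cfg.in_channels, 1, 1), dtype=dtype)
        for b in range(cfg.out_channels):
            lift[b, b % cfg.in_channels, 0, 0] = 1.0
        self._lift = Tensor(lift)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        factor = 2**self.cfg.n_stages
        if h % factor or w % factor:
            raise ValueError(
                f"spatial size {h}×{w} must be divisible by 2^{self.cfg.n_stages}"
            )
        f = self.stem(x)
        skips = []
        for stack, down in zip(self.enc_stacks, self.downs):
            f = stack(f)
            skips.append(f)
            f = down(f)
        f = self.bottleneck(f)
        for up, gate, merge, stack, skip in zip(
            self.ups, self.skip_gates, self.merges, self.dec_stacks,
            reversed(skips),
        ):
            f = up(f)
            f = merge(concat([f, gate(skip)], axis=1))
            f = stack(f)
        return self.head(f) + conv2d(x, self._lift)
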