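"""The attention-heavy branch used twice: reconstructing the illuminant cube
from the light RGB, and decoding the fused (channel-concatenated) cubes into
reflectance.

Two distinctly parameterised shallow 3×3 paths (each conv → ReLU → channel
attention → spatial attention) are refined by 1×1 paths, the four feature
maps are concatenated, refined by N recursive residual attention L-blocks,
and projected to the output bands by a 1×1 head.  The light-role and
decoder-role instances share this code but never parameters — their input
widths differ (3 vs 2B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Conv2d, Module, Tensor, concat
from .blocks import ChannelGate, LBlock, SpatialGate

__all__ = ["SpectralNetConfig", "AttentionSpectralNet"]


@dataclass(frozen=True)
class SpectralNetConfig:
    """Architecture hyperparameters of an attention-branch instance."""

    in_channels: int = 3
    out_channels: int = 32
    width: int = 64  # per-branch width; fused width is 4× this
    n_lblocks: int = 3
    use_attention: bool = True  # identity gates when disabled (ablation)

    def __post_init__(self) -> None:
        if self.n_lblocks < 1 or self.width < 1 or self.in_channels < 1:
            raise ValueError("width, channels and n_lblocks must be ≥ 1")


class _AttnPair(Module):
    def __init__(self, use_attention: bool, rng, dtype):
        from ..nn import Identity

        self.ca = ChannelGate(rng=rng, dtype=dtype) if use_attention else Identity()
        self.sa = SpatialGate(rng=rng, dtype=dtype) if use_attention else Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.sa(self.ca(x))


class AttentionSpectralNet(Module):
    """Maps (N, in_channels, H, W) to cubes (N, out_channels, H, W)."""

    def __init__(self, cfg: SpectralNetConfig, seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        w = cfg.width
        self.branch1 = Conv2d(cfg.in_channels, w, 3, rng=rng, dtype=dtype)
        self.branch2 = Conv2d(cfg.in_channels, w, 3, rng=rng, dtype=dtype)
        self.attn1 = _AttnPair(cfg.use_attention, rng, dtype)
        self.attn2 = _AttnPair(cfg.use_attention, rng, dtype)
        self.refine3 = Conv2d(w, w, 1, rng=rng, dtype=dtype)
        self.refine4 = Conv2d(w, w, 1, rng=rng, dtype=dtype)
        self.attn3 = _AttnPair(cfg.use_attention, rng, dtype)
        self.attn4 = _AttnPair(cfg.use_attention, rng, dtype)
        fused = 4 * w
        self.fused_width = fused  # == sum of the four branch widths
        self.lblocks = [LBlock(fused, rng=rng, dtype=dtype)
                        for _ in range(cfg.n_lblocks)]
        if not cfg.use_attention:
            for block in self.lblocks:
                from ..nn import Identity

                block.ca = Identity()
                block.sa = Identity()
        self.head = Conv2d(fused, cfg.out_channels, 1, rng=rng, dtype=dtype,
                           init_scale=0.1)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        f1 = self.attn1(self.branch1(x).relu())
        f2 = self.attn2(self.branch2(x).relu())
        f3 = self.attn3(self.refine3(f1).relu())
        f4 = self.attn4(self.refine4(f2).relu())
        fused = concat([f1, f2, f3, f4], axis=1)
        assert fused.shape[1] == self.fused_width
        for block in self.lblocks:
            fused = block(fused)
        return self.head(fused)
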