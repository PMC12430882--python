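"""Baseline: a plain encoder–decoder U-Net without attention.

Predicts the reflectance cube directly from the sample RGB alone — the
reference architecture the physics-informed two-branch model is compared
against under matched training budgets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Conv2d, ConvTranspose2d, Module, Sequential, Tensor, concat

__all__ = ["PlainUNetConfig", "PlainUNet"]


@dataclass(frozen=True)
class PlainUNetConfig:
    in_channels: int = 3
    out_channels: int = 32
    base_width: int = 32
    n_stages: int = 3

    def __post_init__(self) -> None:
        if self.n_stages < 1 or self.base_width < 1:
            raise ValueError("n_stages and base_width must be ≥ 1")


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng, dtype):
        self.c1 = Conv2d(cin, cout, 3, rng=rng, dtype=dtype)
        self.c2 = Conv2d(cout, cout, 3, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class PlainUNet(Module):
    """Classic U-Net shape: double-conv stages, strided-conv downsampling,
    transposed-conv upsampling with skip concatenation, 1×1 head."""

    def __init__(self, cfg: PlainUNetConfig, seed: int = 0, dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        widths = [cfg.base_width * 2**i for i in range(cfg.n_stages + 1)]
        self.enc = [_DoubleConv(cfg.in_channels if i == 0 else widths[i - 1],
                                widths[i], rng, dtype)
                    for i in range(cfg.n_stages)]
        self.downs = [Conv2d(widths[i], widths[i], 3, stride=2, padding=1,
                             rng=rng, dtype=dtype)
                      for i in range(cfg.n_stages)]
        self.bottleneck = _DoubleConv(widths[-2], widths[-1], rng, dtype)
        self.ups = [ConvTranspose2d(widths[i + 1], widths[i], rng=rng, dtype=dtype)
                    for i in reversed(range(cfg.n_stages))]
        self.dec = [_DoubleConv(2 * widths[i], widths[i], rng, dtype)
                    for i in reversed(range(cfg.n_stages))]
        self.head = Conv2d(widths[0], cfg.out_channels, 1, rng=rng, dtype=dtype,
                           init_scale=0.1)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        factor = 2**self.cfg.n_stages
        if h % factor or w % factor:
            raise ValueError(
                f"spatial size {h}×{w} must be divisible by 2^{self.cfg.n_stages}"
            )
        skips = []
        f = x
        for enc, down in zip(self.enc, self.downs):
            f = enc(f)
            skips.append(f)
            f = down(f)
        f = self.bottleneck(f)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            f = dec(concat([up(f), skip], axis=1))
        return self.head(f)
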