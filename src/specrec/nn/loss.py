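"""Differentiable training losses mirroring :mod:`specrec.metrics`.

The windowed SSIM term filters local statistics with a fixed (non-trainable)
window kernel through the autograd convolution, so gradients flow to the
prediction while the window itself stays constant.  Numerical agreement with
the numpy evaluation path is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

from ..metrics import LossConfig, ssim_window_1d
from .autograd import Tensor, corr1d_valid

__all__ = ["mse_loss", "ssim_loss", "ssim_mean", "structure_pixel_loss"]


def mse_loss(pred: Tensor, truth: Tensor) -> Tensor:
    """Mean squared difference over every element."""
    diff = pred - truth
    return (diff * diff).mean()


def _local(x: Tensor, win1d: np.ndarray) -> Tensor:
    # the window is an outer product, so filter separably along H then W
    return corr1d_valid(corr1d_valid(x, win1d, axis=2), win1d, axis=3)


def ssim_mean(pred: Tensor, truth: Tensor, cfg: LossConfig | None = None) -> Tensor:
    """Mean windowed SSIM over all bands and interior window positions."""
    cfg = LossConfig() if cfg is None else cfg
    n, c, h, w = pred.shape
    if min(h, w) < cfg.window_size:
        raise ValueError(f"spatial size {h}×{w} smaller than SSIM window")
    win = ssim_window_1d(cfg)
    mu_x = _local(pred, win)
    mu_y = _local(truth, win)
    s_xx = _local(pred * pred, win) - mu_x * mu_x
    s_yy = _local(truth * truth, win) - mu_y * mu_y
    s_xy = _local(pred * truth, win) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + cfg.C1) * (2.0 * s_xy + cfg.C2)
    den = (mu_x * mu_x + mu_y * mu_y + cfg.C1) * (s_xx + s_yy + cfg.C2)
    return (num / den).mean()


def ssim_loss(pred: Tensor, truth: Tensor, cfg: LossConfig | None = None) -> Tensor:
    """1 − mean SSIM."""
    return 1.0 - ssim_mean(pred, truth, cfg)


def structure_pixel_loss(pred: Tensor, truth: Tensor,
                         cfg: LossConfig | None = None) -> Tensor:
    """The composite α·MSE + β·(1 − SSIM) training loss."""
    cfg = LossConfig() if cfg is None else cfg
    total = cfg.alpha * mse_loss(pred, truth)
    if cfg.beta > 0:
        total = total + cfg.beta * ssim_loss(pred, truth, cfg)
    return total
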