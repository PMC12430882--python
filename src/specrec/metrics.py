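"""Evaluation metrics: MSE, windowed SSIM, the composite structure–pixel loss,
and per-band metric tables.

SSIM follows the standard windowed form

    SSIM(x, y) = (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2))

with local statistics taken over an 11×11 Gaussian window (σ = 1.5) by
default, averaged over all fully interior window positions.  The stabiliser
constants default to C1 = 1e-4 and C2 = 9e-4, which assume inputs scaled to
[0, 1].  A uniform-window mode is provided for oracle comparisons.  The
composite training loss is α·MSE + β·(1 − SSIM) with α = β = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossConfig",
    "BandMetrics",
    "mse",
    "ssim",
    "ssim_window",
    "ssim_window_1d",
    "loss_overall",
    "evaluate_bands",
    "relative_improvement",
]


@dataclass(frozen=True)
class LossConfig:
    """Weights and SSIM parameters of the structure–pixel loss."""

    alpha: float = 1.0  # MSE weight
    beta: float = 1.0  # SSIM-loss weight
    C1: float = 1e-4
    C2: float = 9e-4
    window_size: int = 11
    window_kind: str = "gaussian"  # or "uniform"
    gaussian_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.C1 <= 0 or self.C2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and ≥ 3")
        if self.window_kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown window kind {self.window_kind!r}")


@dataclass
class BandMetrics:
    """Per-band MSE and SSIM vectors plus their means."""

    mse_per_band: np.ndarray
    ssim_per_band: np.ndarray

    @property
    def mean_mse(self) -> float:
        return float(self.mse_per_band.mean())

    @property
    def mean_ssim(self) -> float:
        return float(self.ssim_per_band.mean())


def _as_array(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=float)


def mse(pred, truth) -> float:
    """Mean squared elementwise difference over all pixels and bands."""
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def ssim_window_1d(cfg: LossConfig) -> np.ndarray:
    """Normalized 1-D window; the 2-D window is its outer product."""
    k = cfg.window_size
    if cfg.window_kind == "uniform":
        win = np.ones(k)
    else:
        r = np.arange(k) - (k - 1) / 2
        win = np.exp(-0.5 * (r / cfg.gaussian_sigma) ** 2)
    return win / win.sum()


def ssim_window(cfg: LossConfig) -> np.ndarray:
    """The normalized 2-D weighting window used for local SSIM statistics."""
    win1d = ssim_window_1d(cfg)
    return np.outer(win1d, win1d)


def ssim(x, y, cfg: LossConfig | None = None) -> float:
    """Windowed SSIM between two single-band images, in (−1, 1].

    Local weighted means, variances and covariance are computed at every
    fully interior window position and the SSIM map is averaged.
    """
    cfg = LossConfig() if cfg is None else cfg
    xa, ya = _as_array(x), _as_array(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    if xa.ndim != 2:
        raise ValueError("ssim expects single-band 2-D images")
    k = cfg.window_size
    if min(xa.shape) < k:
        raise ValueError(f"image {xa.shape} smaller than {k}×{k} window")
    win = ssim_window(cfg)

    def local(img: np.ndarray) -> np.ndarray:
        v = np.lib.stride_tricks.sliding_window_view(img, (k, k))
        return np.einsum("hwij,ij->hw", v, win)

    mu_x, mu_y = local(xa), local(ya)
    s_xx = local(xa * xa) - mu_x**2
    s_yy = local(ya * ya) - mu_y**2
    s_xy = local(xa * ya) - mu_x * mu_y
    num = (2 * mu_x * mu_y + cfg.C1) * (2 * s_xy + cfg.C2)
    den = (mu_x**2 + mu_y**2 + cfg.C1) * (s_xx + s_yy + cfg.C2)
    return float(np.mean(num / den))


def _per_band(pred, truth, cfg: LossConfig) -> tuple[np.ndarray, np.ndarray]:
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.ndim == 2:
        p, t = p[..., None], t[..., None]
    n_bands = p.shape[2]
    mses = np.array([mse(p[..., b], t[..., b]) for b in range(n_bands)])
    ssims = np.array([ssim(p[..., b], t[..., b], cfg) for b in range(n_bands)])
    return mses, ssims


def loss_overall(pred, truth, cfg: LossConfig | None = None) -> float:
    """The structure–pixel loss α·MSE + β·mean over bands of (1 − SSIM).

    Zero iff pred equals truth (for α, β > 0); for cubes the SSIM term is
    computed per band and averaged.
    """
    cfg = LossConfig() if cfg is None else cfg
    total = cfg.alpha * mse(pred, truth)
    if cfg.beta > 0:
        _, ssims = _per_band(pred, truth, cfg)
        total += cfg.beta * float(np.mean(1.0 - ssims))
    return float(total)


def evaluate_bands(pred, truth, cfg: LossConfig | None = None) -> BandMetrics:
    """Per-band MSE and SSIM between two cubes (plus means via BandMetrics)."""
    cfg = LossConfig() if cfg is None else cfg
    mses, ssims = _per_band(pred, truth, cfg)
    return BandMetrics(mse_per_band=mses, ssim_per_band=ssims)


def relative_improvement(a: float, b: float) -> float:
    """Relative improvement of ``a`` over ``b`` in percent: 100·(a − b)/b."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (a - b) / b


def band_metrics_to_csv(metrics: BandMetrics, path) -> None:
    """Write a (band, mse, ssim) CSV table."""
    rows = ["band,mse,ssim"]
    for b, (m, s) in enumerate(zip(metrics.mse_per_band, metrics.ssim_per_band)):
        rows.append(f"{b},{m:.10g},{s:.10g}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
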