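"""Discrete image-formation model and its pointwise inversion.

The forward model is the discretised camera equation

    G[x, y, k] = Σ_λ I(λ) · S(x, y, λ) · C_k(λ)

mapping a spectral radiance cube through per-channel sensitivities to a
3-channel image.  Imaging a diffuse white reference (S ≡ 1) under the same
light measures the illuminant term directly, and the per-band ratio of the
two measured cubes recovers reflectance:

    S(x, y, λ) = L_sample(x, y, λ) / L_light(x, y, λ)

These few operations are the physical ground truth every synthetic sample and
every network prediction in this package is checked against.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import interp1d

from .core import (
    CameraResponse,
    GridMismatchError,
    IlluminantCube,
    IlluminantSpectrum,
    RadianceCube,
    ReflectanceCube,
    RGBImage,
    WavelengthGrid,
    _check_grids,
)

__all__ = [
    "render_rgb",
    "make_radiance",
    "compute_reflectance",
    "normalize_unit_max",
    "resample_spectrum",
    "DEFAULT_DIVISION_FLOOR",
]

#: Division floor applied to illuminant cubes normalised to unit maximum.
DEFAULT_DIVISION_FLOOR = 1e-6


def render_rgb(cube: RadianceCube | IlluminantCube, response: CameraResponse) -> RGBImage:
    """Project a spectral cube to a linear RGB image through the camera response.

    ``out[x, y, k] = Σ_λ cube[x, y, λ] · C_k(λ)`` — linear in the cube.
    """
    _check_grids(cube.grid, response.grid, "render_rgb")
    rgb = np.einsum("hwb,kb->hwk", cube.values, response.sensitivities)
    return RGBImage(rgb)


def make_radiance(
    reflectance: ReflectanceCube, illum: IlluminantSpectrum | IlluminantCube
) -> RadianceCube:
    """Elementwise product I(λ)·S(x, y, λ); a spectrum is broadcast to all pixels."""
    _check_grids(reflectance.grid, illum.grid, "make_radiance")
    if isinstance(illum, IlluminantSpectrum):
        illum_values = illum.power[None, None, :]
    else:
        illum_values = illum.values
        if illum_values.shape != reflectance.values.shape:
            raise ValueError(
                f"illuminant cube shape {illum_values.shape} does not match "
                f"reflectance shape {reflectance.values.shape}"
            )
    return RadianceCube(reflectance.values * illum_values, reflectance.grid)


def compute_reflectance(
    sample: RadianceCube,
    illum: IlluminantCube | IlluminantSpectrum,
    floor: float = DEFAULT_DIVISION_FLOOR,
    return_mask: bool = False,
):
    """Per-pixel, per-band ratio of a sample cube to the illuminant cube.

    Bands where the illuminant does not exceed ``floor`` are clamped to the
    floor before dividing (never a division by zero); with
    ``return_mask=True`` the boolean mask of clamped positions is returned
    alongside the cube.

    Wherever the illuminant exceeds the floor this inverts
    :func:`make_radiance` exactly:
    ``compute_reflectance(make_radiance(S, I), I) == S``.
    """
    if floor <= 0:
        raise ValueError("floor must be strictly positive")
    _check_grids(sample.grid, illum.grid, "compute_reflectance")
    if isinstance(illum, IlluminantSpectrum):
        illum_values = np.broadcast_to(illum.power, sample.values.shape)
    else:
        illum_values = illum.values
        if illum_values.shape != sample.values.shape:
            raise ValueError(
                f"illuminant cube shape {illum_values.shape} does not match "
                f"sample shape {sample.values.shape}"
            )
    clamped = illum_values <= floor
    denom = np.maximum(illum_values, floor)
    cube = ReflectanceCube(sample.values / denom, sample.grid)
    if return_mask:
        return cube, clamped
    return cube


def normalize_unit_max(image):
    """Scale an image or cube so its maximum value is exactly 1 (θ / max θ).

    Accepts :class:`RGBImage`, :class:`RadianceCube`, :class:`ReflectanceCube`
    or :class:`IlluminantCube` and returns the same type.  Idempotent and
    scale-invariant; all-zero input is rejected.
    """
    peak = float(image.values.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero image")
    scaled = image.values / peak
    if isinstance(image, RGBImage):
        return RGBImage(scaled)
    return type(image)(scaled, image.grid)


def _resample_values(values: np.ndarray, source: WavelengthGrid, target: WavelengthGrid) -> np.ndarray:
    src = source.band_centers
    tgt = target.band_centers
    if tgt[-1] < src[0] or tgt[0] > src[-1]:
        raise ValueError(
            f"grids are disjoint: source covers [{src[0]}, {src[-1]}] nm, "
            f"target [{tgt[0]}, {tgt[-1]}] nm"
        )
    f = interp1d(src, values, axis=-1, bounds_error=False,
                 fill_value=(values[..., 0], values[..., -1]))
    out = f(tgt)
    # linear interpolation of nonnegative samples stays nonnegative up to rounding
    return np.maximum(out, 0.0)


def resample_spectrum(obj, target: WavelengthGrid):
    """Linearly interpolate a spectrum/cube/response onto a new wavelength grid.

    Used to map finely sampled sources (e.g. a 204-band imager) onto the
    coarse working grid.  Outside the source range values are held at the
    nearest edge band.  Grids must overlap.
    """
    if isinstance(obj, IlluminantSpectrum):
        return IlluminantSpectrum(_resample_values(obj.power, obj.grid, target), target)
    if isinstance(obj, CameraResponse):
        return CameraResponse(
            _resample_values(obj.sensitivities, obj.grid, target), target
        )
    if isinstance(obj, (ReflectanceCube, RadianceCube, IlluminantCube)):
        return type(obj)(_resample_values(obj.values, obj.grid, target), target)
    raise TypeError(f"cannot resample object of type {type(obj).__name__}")
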