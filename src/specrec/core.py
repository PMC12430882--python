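"""Spectral data model: wavelength grids and the cube/spectrum containers.

Everything downstream (scene synthesis, the networks, metrics, I/O) is built
on these containers.  All cubes are channel-last ``H×W×B`` float arrays with a
shared :class:`WavelengthGrid`; RGB images are ``H×W×3`` with channel order
R, G, B.  Values are relative (dimensionless reflectance, relative radiance or
power) — there is no absolute radiometric calibration anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ReflectanceCube",
    "RadianceCube",
    "IlluminantSpectrum",
    "IlluminantCube",
    "CameraResponse",
    "RGBImage",
    "GridMismatchError",
]

#: Wavelength range (nm) any grid must live inside.  Covers the visible range
#: plus the near-infrared tail of handheld spectral imagers.
WAVELENGTH_MIN_NM = 380.0
WAVELENGTH_MAX_NM = 1004.0


class GridMismatchError(ValueError):
    """Raised when two spectral objects carry incompatible wavelength grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """An ordered set of band-centre wavelengths, in nanometres."""

    band_centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers, dtype=float)
        object.__setattr__(self, "band_centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise ValueError("a wavelength grid needs at least 2 bands")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if centers[0] < WAVELENGTH_MIN_NM or centers[-1] > WAVELENGTH_MAX_NM:
            raise ValueError(
                f"band centers must lie within "
                f"[{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm, "
                f"got [{centers[0]}, {centers[-1]}]"
            )

    @classmethod
    def uniform(cls, start_nm: float, stop_nm: float, n_bands: int) -> "WavelengthGrid":
        """Uniformly spaced grid of ``n_bands`` centres from start to stop inclusive."""
        return cls(np.linspace(start_nm, stop_nm, n_bands))

    @classmethod
    def default(cls, n_bands: int = 32) -> "WavelengthGrid":
        """The working grid: ``n_bands`` bands spanning the visible 400–700 nm."""
        return cls.uniform(400.0, 700.0, n_bands)

    @property
    def band_count(self) -> int:
        return int(self.band_centers.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.band_centers.shape == other.band_centers.shape and bool(
            np.allclose(self.band_centers, other.band_centers)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.band_centers.tobytes())

    def __len__(self) -> int:
        return self.band_count


def _check_grids(a_grid: WavelengthGrid, b_grid: WavelengthGrid, what: str) -> None:
    if a_grid != b_grid:
        raise GridMismatchError(
            f"{what}: wavelength grids differ "
            f"({a_grid.band_count} vs {b_grid.band_count} bands)"
        )


def _validate_nonneg_finite(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.dtype not in (np.float32, np.float64):
        values = values.astype(np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(values < 0):
        raise ValueError(f"{name} contains negative values")
    return values


@dataclass
class _Cube:
    """Shared behaviour of rank-3 spectral cubes (values ``H×W×B`` + grid)."""

    values: np.ndarray
    grid: WavelengthGrid

    _name = "cube"

    def __post_init__(self) -> None:
        values = _validate_nonneg_finite(self.values, self._name)
        if values.ndim != 3:
            raise ValueError(f"{self._name} must be H×W×B, got shape {values.shape}")
        if values.shape[2] != self.grid.band_count:
            raise ValueError(
                f"{self._name} has {values.shape[2]} bands but grid has "
                f"{self.grid.band_count}"
            )
        self.values = values

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


class ReflectanceCube(_Cube):
    """Per-pixel spectral reflectance S(x, y, λ), dimensionless.

    Values are not capped at 1: glossy pixels may reflect more than the diffuse
    white reference in some bands.  Nonnegativity is enforced.
    """

    _name = "reflectance cube"


class RadianceCube(_Cube):
    """Per-pixel relative spectral radiance, the product I(λ)·S(x, y, λ)."""

    _name = "radiance cube"


class IlluminantCube(_Cube):
    """Spatially resolved illuminant I(x, y, λ), e.g. a white-board measurement."""

    _name = "illuminant cube"

    @classmethod
    def broadcast(cls, spectrum: "IlluminantSpectrum", height: int, width: int) -> "IlluminantCube":
        """Tile a single illuminant spectrum over an H×W scene."""
        vals = np.broadcast_to(
            spectrum.power, (height, width, spectrum.grid.band_count)
        ).copy()
        return cls(vals, spectrum.grid)


@dataclass
class IlluminantSpectrum:
    """Relative spectral power distribution I(λ) of a light source."""

    power: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        power = _validate_nonneg_finite(self.power, "illuminant power")
        if power.ndim != 1 or power.size != self.grid.band_count:
            raise ValueError(
                f"illuminant power must be a length-{self.grid.band_count} vector"
            )
        if not np.any(power > 0):
            raise ValueError("illuminant must have at least one positive band")
        self.power = power


@dataclass
class CameraResponse:
    """Per-channel spectral sensitivity C_k(λ), rows ordered R, G, B."""

    sensitivities: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        sens = _validate_nonneg_finite(self.sensitivities, "camera sensitivities")
        if sens.shape != (3, self.grid.band_count):
            raise ValueError(
                f"sensitivities must be 3×{self.grid.band_count}, got {sens.shape}"
            )
        if np.any(~sens.any(axis=1)):
            raise ValueError("every channel needs at least one positive band")
        self.sensitivities = sens

    @classmethod
    def gaussian(
        cls,
        grid: WavelengthGrid,
        centers_nm: tuple[float, float, float] = (610.0, 540.0, 460.0),
        width_nm: float = 35.0,
    ) -> "CameraResponse":
        """Generic three-Gaussian RGB camera, peaks at ``centers_nm`` (R, G, B)."""
        lam = grid.band_centers[None, :]
        mu = np.asarray(centers_nm, dtype=float)[:, None]
        sens = np.exp(-0.5 * ((lam - mu) / width_nm) ** 2)
        return cls(sens, grid)


@dataclass
class RGBImage:
    """A linear-light 3-channel image, ``H×W×3``, channel order R, G, B."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = _validate_nonneg_finite(self.values, "RGB image")
        if values.ndim != 3 or values.shape[2] != 3:
            raise ValueError(f"RGB image must be H×W×3, got shape {values.shape}")
        self.values = values

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]
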