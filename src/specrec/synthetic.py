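"""Synthetic spectral-scene simulator.

Generates paired training records with the statistical structure of a
light-box acquisition rig: a bank of 16 LEDs (warm/neutral/cool whites plus
monochromatic hues) mixed into 16 lighting conditions, piecewise-smooth
tooth/ceramic-like reflectance fields, a generic Gaussian RGB camera, and the
rotation/shift/crop augmentation pipeline.  Every record carries five
components — object RGB, light RGB, object spectral cube, light spectral
cube, and the reflectance ground truth computed as their per-band ratio — so
supervised training and evaluation run entirely from code, without any
captured data.

LED spectra are Gaussian mixtures with hand-chosen centres and widths; only
the qualitative class structure (warm vs. neutral vs. cool whites,
monochromatic hues) is modelled, not measured spectral power distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CameraResponse,
    IlluminantCube,
    IlluminantSpectrum,
    RadianceCube,
    ReflectanceCube,
    RGBImage,
    WavelengthGrid,
)
from .physics import compute_reflectance, make_radiance, render_rgb

__all__ = [
    "LEDSpec",
    "LightingCondition",
    "SceneParams",
    "PairedSample",
    "builtin_led_bank",
    "builtin_conditions",
    "condition_spectrum",
    "sample_reflectance_field",
    "render_pair",
    "augment",
    "build_dataset",
    "split_sizes",
]

AUGMENT_OPS = ("rotate", "shift", "crop")


@dataclass(frozen=True)
class LEDSpec:
    """One LED: a Gaussian-mixture emission spectrum with a qualitative class."""

    id: int
    kind: str  # warm_white | neutral_white | cool_white | monochromatic
    peaks: tuple[tuple[float, float, float], ...]  # (center nm, width nm, amplitude)

    def spectrum(self, grid: WavelengthGrid) -> IlluminantSpectrum:
        lam = grid.band_centers
        power = np.zeros_like(lam)
        for center, width, amp in self.peaks:
            if amp < 0:
                raise ValueError("LED peak amplitudes must be nonnegative")
            power = power + amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
        return IlluminantSpectrum(power, grid)


@dataclass(frozen=True)
class LightingCondition:
    """A named nonnegative mixture of LEDs from the bank."""

    name: str
    members: tuple[tuple[int, float], ...]  # (led id, mixing weight)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a lighting condition needs at least one LED")
        if any(w < 0 for _, w in self.members):
            raise ValueError("mixing weights must be nonnegative")


def _white_peaks(blue_amp: float, phosphor_nm: float, phosphor_amp: float,
                 phosphor_width: float = 65.0) -> tuple:
    """White LED = narrow blue pump (~450 nm) + broad phosphor emission."""
    return ((450.0, 12.0, blue_amp), (phosphor_nm, phosphor_width, phosphor_amp))


def builtin_led_bank() -> list[LEDSpec]:
    """The 16-LED bank: ids 1–16 across warm/neutral/cool white and 8 hues.

    Warm whites (6, 11, 16) put most of their phosphor energy at long
    wavelengths, cool whites (1, 4) keep a dominant blue pump, neutral whites
    (7, 10, 13) sit between.  The remaining ids are monochromatic Gaussians
    spread over distinct hues.
    """
    leds = {
        # cool whites: strong blue pump, modest mid phosphor
        1: LEDSpec(1, "cool_white", _white_peaks(1.0, 545.0, 0.45)),
        4: LEDSpec(4, "cool_white", _white_peaks(1.0, 555.0, 0.55)),
        # neutral whites
        7: LEDSpec(7, "neutral_white", _white_peaks(0.8, 565.0, 0.75)),
        10: LEDSpec(10, "neutral_white", _white_peaks(0.7, 570.0, 0.80)),
        13: LEDSpec(13, "neutral_white", _white_peaks(0.75, 575.0, 0.70)),
        # warm whites: weak blue pump, strong long-wavelength phosphor
        6: LEDSpec(6, "warm_white", _white_peaks(0.35, 600.0, 1.0, 70.0)),
        11: LEDSpec(11, "warm_white", _white_peaks(0.30, 610.0, 1.0, 75.0)),
        16: LEDSpec(16, "warm_white", _white_peaks(0.40, 595.0, 0.95, 70.0)),
    }
    mono_centers = {2: 420.0, 3: 470.0, 5: 500.0, 8: 530.0,
                    9: 560.0, 12: 590.0, 14: 630.0, 15: 665.0}
    for led_id, center in mono_centers.items():
        leds[led_id] = LEDSpec(led_id, "monochromatic", ((center, 14.0, 1.0),))
    return [leds[i] for i in range(1, 17)]


def builtin_conditions() -> list[LightingCondition]:
    """The 16 lighting conditions: 8 single whites, 5 binary white mixes,
    2 tricolor white mixes, and one eleven-LED multicolor mix."""
    singles = [6, 11, 16, 7, 10, 13, 1, 4]  # 3 warm, 3 neutral, 2 cool
    binaries = [(7, 6), (6, 1), (7, 1), (7, 4), (6, 4)]
    tricolors = [(7, 6, 1), (7, 6, 4)]
    eleven = (1, 2, 3, 5, 6, 7, 8, 9, 12, 14, 15)
    conditions: list[LightingCondition] = []
    for i in singles:
        conditions.append(LightingCondition(f"single_{i}", ((i, 1.0),)))
    for pair in binaries:
        conditions.append(
            LightingCondition("mix_" + "-".join(map(str, pair)),
                              tuple((i, 1.0) for i in pair))
        )
    for tri in tricolors:
        conditions.append(
            LightingCondition("tri_" + "-".join(map(str, tri)),
                              tuple((i, 1.0) for i in tri))
        )
    conditions.append(
        LightingCondition("multi_11", tuple((i, 1.0) for i in eleven))
    )
    return conditions


def condition_spectrum(
    condition: LightingCondition,
    grid: WavelengthGrid,
    bank: list[LEDSpec] | None = None,
) -> IlluminantSpectrum:
    """Evaluate a condition's mixed spectral power distribution on a grid."""
    bank = builtin_led_bank() if bank is None else bank
    by_id = {led.id: led for led in bank}
    power = np.zeros(grid.band_count)
    for led_id, weight in condition.members:
        power = power + weight * by_id[led_id].spectrum(grid).power
    return IlluminantSpectrum(power, grid)


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the scene generator.

    Defaults emulate the acquisition described for the dental rig: 64×64
    scenes, 32 working bands over 400–700 nm, a handful of smooth elliptical
    specimens per scene, mild sensor noise on the RGB images only.
    """

    image_size: int = 64
    n_bands: int = 32
    n_blobs: int = 3
    n_basis: int = 4  # smooth spectral basis functions per region
    background_reflectance: float = 0.08
    noise_sigma: float = 0.01
    augment_ops: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.n_bands < 2:
            raise ValueError("image_size must be positive and n_bands ≥ 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.uniform(400.0, 700.0, self.n_bands)


@dataclass
class PairedSample:
    """One five-component training record.

    ``reflectance_gt`` is the per-band ratio of the object cube to the light
    cube; both RGB images are renders of the corresponding cubes through the
    generating camera (plus optional sensor noise).
    """

    sample_rgb: RGBImage
    light_rgb: RGBImage
    sample_hsi: RadianceCube
    light_hsi: IlluminantCube
    reflectance_gt: ReflectanceCube
    condition: LightingCondition
    seed: int

    def validate(self, atol: float = 1e-8) -> None:
        """Check the record's internal physical consistency."""
        h, w, _ = self.sample_hsi.shape
        for name, arr in [
            ("sample_rgb", self.sample_rgb.values),
            ("light_rgb", self.light_rgb.values),
            ("light_hsi", self.light_hsi.values),
            ("reflectance_gt", self.reflectance_gt.values),
        ]:
            if arr.shape[:2] != (h, w):
                raise ValueError(f"{name} spatial size {arr.shape[:2]} != {(h, w)}")
        ratio = compute_reflectance(self.sample_hsi, self.light_hsi)
        if not np.allclose(ratio.values, self.reflectance_gt.values, atol=atol):
            raise ValueError("reflectance_gt is not the cube ratio")


def _smooth_basis(grid: WavelengthGrid, n_basis: int) -> np.ndarray:
    """Broad overlapping Gaussian bumps spanning the grid, rows = basis."""
    lam = grid.band_centers
    centers = np.linspace(lam[0], lam[-1], n_basis)
    width = (lam[-1] - lam[0]) / max(n_basis - 1, 1) * 0.9
    return np.exp(-0.5 * ((lam[None, :] - centers[:, None]) / width) ** 2)


def sample_reflectance_field(params: SceneParams, seed: int) -> ReflectanceCube:
    """Draw a piecewise-smooth reflectance scene: elliptical specimen blobs on
    a dark constant background.

    Each blob's spectrum is a nonnegative combination of a few broad spectral
    basis functions plus an upward ramp toward long wavelengths (the
    characteristic tooth/ceramic slope); blob edges are softened so spatial
    transitions are smooth.  The background is a dark, smoothly tinted
    spectrum drawn per scene — deliberately *not* a flat gray, so no scene
    contains a built-in calibration reference that would let a model infer
    the illuminant without the light image.  Values lie in [0, 1.2].
    Deterministic in seed.
    """
    rng = np.random.default_rng(seed)
    size, grid = params.image_size, params.grid
    lam = grid.band_centers
    ramp = (lam - lam[0]) / (lam[-1] - lam[0])  # 0 → 1 toward long wavelengths
    basis = _smooth_basis(grid, params.n_basis)

    bg_level = params.background_reflectance * rng.uniform(0.5, 1.5)
    bg_shape = rng.uniform(0.0, 1.0, params.n_basis) @ basis
    bg_shape = bg_shape / bg_shape.mean()
    bg_spectrum = np.clip(bg_level * bg_shape, 0.02, 0.3)
    cube = np.broadcast_to(bg_spectrum, (size, size, grid.band_count)).copy()
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(params.n_blobs):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
        ay, ax = rng.uniform(0.12 * size, 0.32 * size, size=2)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        r2 = (u / ay) ** 2 + (v / ax) ** 2
        mask = 1.0 / (1.0 + np.exp((r2 - 1.0) * 8.0))  # soft ellipse edge
        coeffs = rng.uniform(0.0, 0.5, size=params.n_basis)
        slope = rng.uniform(0.2, 0.5)
        level = rng.uniform(0.25, 0.6)
        spectrum = level + slope * ramp + coeffs @ basis
        spectrum = np.clip(spectrum, 0.0, 1.2)
        cube = cube * (1 - mask[..., None]) + mask[..., None] * spectrum[None, None, :]
    return ReflectanceCube(np.clip(cube, 0.0, 1.2), grid)


def render_pair(
    reflectance: ReflectanceCube,
    condition: LightingCondition,
    response: CameraResponse,
    noise_sigma: float = 0.0,
    seed: int = 0,
    bank: list[LEDSpec] | None = None,
) -> PairedSample:
    """Image a reflectance scene under one lighting condition.

    Builds the light cube (the condition spectrum, scaled to unit maximum and
    broadcast over the scene), the object cube as their product, and both RGB
    renders.  Seeded Gaussian sensor noise is added to the RGB images only;
    the spectral cubes and the reflectance ground truth stay noise-free.
    """
    grid = reflectance.grid
    spectrum = condition_spectrum(condition, grid, bank)
    spectrum = IlluminantSpectrum(spectrum.power / spectrum.power.max(), grid)
    h, w, _ = reflectance.shape
    light_hsi = IlluminantCube.broadcast(spectrum, h, w)
    sample_hsi = make_radiance(reflectance, spectrum)
    sample_rgb = render_rgb(sample_hsi, response)
    light_rgb = render_rgb(light_hsi, response)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = float(light_rgb.values.max())
        for img in (sample_rgb, light_rgb):
            noisy = img.values + rng.normal(0.0, noise_sigma * scale, img.values.shape)
            img.values = np.maximum(noisy, 0.0)
    return PairedSample(
        sample_rgb=sample_rgb,
        light_rgb=light_rgb,
        sample_hsi=sample_hsi,
        light_hsi=light_hsi,
        reflectance_gt=compute_reflectance(sample_hsi, light_hsi),
        condition=condition,
        seed=seed,
    )


def _rotate(arr: np.ndarray, quarter_turns: int) -> np.ndarray:
    return np.rot90(arr, k=quarter_turns, axes=(0, 1))


def _shift(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def _crop(arr: np.ndarray, y0: int, x0: int, size: int) -> np.ndarray:
    out = np.zeros_like(arr)
    out[:size, :size] = arr[y0 : y0 + size, x0 : x0 + size]
    return out


def augment(pair: PairedSample, ops: list[str], seed: int = 0) -> PairedSample:
    """Apply an identical random geometric transform to the spatial modalities.

    ``ops`` is a subset of {rotate, shift, crop}; rotation is quantised to
    multiples of 90° so spectra are never interpolated; shifts and crops pad
    with zero.  The light images are left untouched — illumination is
    scene-global, not tied to pixel positions.  Output size is preserved.
    """
    unknown = set(ops) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    if not ops:
        return pair
    rng = np.random.default_rng(seed)
    h = pair.sample_hsi.shape[0]
    transforms = []
    if "rotate" in ops:
        k = int(rng.integers(0, 4))
        transforms.append(lambda a, k=k: _rotate(a, k))
    if "shift" in ops:
        dy, dx = (int(v) for v in rng.integers(-h // 4, h // 4 + 1, size=2))
        transforms.append(lambda a, dy=dy, dx=dx: _shift(a, dy, dx))
    if "crop" in ops:
        size = int(rng.integers(max(h // 2, 1), h + 1))
        y0, x0 = (int(v) for v in rng.integers(0, h - size + 1, size=2))
        transforms.append(lambda a, y0=y0, x0=x0, s=size: _crop(a, y0, x0, s))

    def apply(arr: np.ndarray) -> np.ndarray:
        for t in transforms:
            arr = t(arr)
        return arr

    grid = pair.sample_hsi.grid
    return PairedSample(
        sample_rgb=RGBImage(apply(pair.sample_rgb.values)),
        light_rgb=pair.light_rgb,
        sample_hsi=RadianceCube(apply(pair.sample_hsi.values), grid),
        light_hsi=pair.light_hsi,
        reflectance_gt=ReflectanceCube(apply(pair.reflectance_gt.values), grid),
        condition=pair.condition,
        seed=pair.seed,
    )


def split_sizes(n_pairs: int) -> tuple[int, int, int]:
    """Train/val/test sizes, the 3000/300/100 protocol scaled proportionally."""
    train = int(round(n_pairs * 3000 / 3400))
    val = int(round(n_pairs * 300 / 3400))
    val = max(val, 1) if n_pairs >= 3 else val
    test = n_pairs - train - val
    if test < 1 and n_pairs >= 3:
        train -= 1 - test
        test = 1
    return train, val, test


def build_dataset(
    n_pairs: int,
    conditions: list[LightingCondition] | None = None,
    params: SceneParams | None = None,
    seed: int = 0,
    response: CameraResponse | None = None,
) -> tuple[list[PairedSample], list[dict]]:
    """Generate ``n_pairs`` paired records, round-robin over the conditions.

    Returns the records and a manifest (one dict per pair: index, seeds,
    condition, split assignment).  Bit-reproducible from (seed, params,
    conditions).  The default full-scale preset — 4000 pairs of 64×64 scenes
    with 32 bands — matches the emulated acquisition campaign; the split
    follows the 3000/300/100 train/val/test protocol scaled to ``n_pairs``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    conditions = builtin_conditions() if conditions is None else conditions
    params = SceneParams() if params is None else params
    response = (
        CameraResponse.gaussian(params.grid) if response is None else response
    )
    n_train, n_val, _ = split_sizes(n_pairs)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_pairs) % (2**31)
    pairs: list[PairedSample] = []
    manifest: list[dict] = []
    for i in range(n_pairs):
        condition = conditions[i % len(conditions)]
        scene_seed = int(child_seeds[2 * i])
        noise_seed = int(child_seeds[2 * i + 1])
        reflectance = sample_reflectance_field(params, scene_seed)
        pair = render_pair(
            reflectance, condition, response,
            noise_sigma=params.noise_sigma, seed=noise_seed,
        )
        if params.augment_ops:
            pair = augment(pair, list(params.augment_ops), seed=noise_seed)
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        pairs.append(pair)
        manifest.append(
            {
                "index": i,
                "condition": condition.name,
                "scene_seed": scene_seed,
                "noise_seed": noise_seed,
                "split": split,
            }
        )
    return pairs, manifest


def write_manifest(manifest: list[dict], path) -> None:
    """Write a manifest as JSON lines, one record per pair."""
    with open(path, "w") as fh:
        for record in manifest:
            fh.write(json.dumps(record) + "\n")
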