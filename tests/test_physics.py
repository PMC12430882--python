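"""The discrete image-formation model and its pointwise inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specrec import (CameraResponse, GridMismatchError, IlluminantCube,
                     IlluminantSpectrum, RadianceCube, ReflectanceCube,
                     RGBImage, WavelengthGrid)
from specrec.physics import (compute_reflectance, make_radiance,
                             normalize_unit_max, render_rgb, resample_spectrum)


def brute_force_render(cube: np.ndarray, sens: np.ndarray) -> np.ndarray:
    """Independent nested-loop projection oracle."""
    h, w, b = cube.shape
    out = np.zeros((h, w, 3))
    for y in range(h):
        for x in range(w):
            for k in range(3):
                for lam in range(b):
                    out[y, x, k] += cube[y, x, lam] * sens[k, lam]
    return out


class TestRenderRGB:
    def test_zero_cube_renders_black(self, grid8, rng):
        cube = RadianceCube(np.zeros((4, 4, 8)), grid8)
        response = CameraResponse(rng.uniform(0, 1, (3, 8)), grid8)
        assert np.all(render_rgb(cube, response).values == 0)

    def test_indicator_response_picks_one_band(self):
        grid = WavelengthGrid.uniform(450, 650, 2)
        cube = RadianceCube(np.ones((2, 2, 2)), grid)
        sens = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        rgb = render_rgb(cube, CameraResponse(sens, grid))
        assert np.allclose(rgb.values[..., 0], 1.0)
        assert np.allclose(rgb.values[..., 1], 1.0)
        assert np.allclose(rgb.values[..., 2], 2.0)

    def test_matches_nested_loop_oracle(self, rng):
        grid = WavelengthGrid.uniform(400, 700, 4)
        cube = RadianceCube(rng.uniform(0, 2, (5, 3, 4)), grid)
        response = CameraResponse(rng.uniform(0, 1, (3, 4)), grid)
        expected = brute_force_render(cube.values, response.sensitivities)
        assert np.allclose(render_rgb(cube, response).values, expected,
                           rtol=1e-12)

    def test_grid_mismatch_names_band_counts(self, grid8, rng):
        cube = RadianceCube(np.ones((2, 2, 8)), grid8)
        other = WavelengthGrid.uniform(400, 700, 6)
        response = CameraResponse(rng.uniform(0.1, 1, (3, 6)), other)
        with pytest.raises(GridMismatchError, match="8.*6"):
            render_rgb(cube, response)


class TestMakeRadiance:
    def test_unit_reflectance_is_whiteboard(self, grid8, rng):
        reflectance = ReflectanceCube(np.ones((3, 4, 8)), grid8)
        illum = IlluminantSpectrum(rng.uniform(0.1, 1, 8), grid8)
        radiance = make_radiance(reflectance, illum)
        assert np.array_equal(radiance.values,
                              np.broadcast_to(illum.power, (3, 4, 8)))

    def test_zero_illuminant_cube_gives_zero_radiance(self, grid8):
        reflectance = ReflectanceCube(np.full((3, 3, 8), 0.7), grid8)
        illum = IlluminantCube(np.zeros((3, 3, 8)), grid8)
        assert np.all(make_radiance(reflectance, illum).values == 0)

    def test_elementwise_oracle(self, random_scene):
        reflectance, illum, _ = random_scene
        radiance = make_radiance(reflectance, illum)
        for y in range(reflectance.shape[0]):
            for x in range(reflectance.shape[1]):
                assert np.allclose(
                    radiance.values[y, x],
                    reflectance.values[y, x] * illum.power,
                )


class TestComputeReflectance:
    def test_whiteboard_self_ratio_is_one(self, grid8, rng):
        values = rng.uniform(0.2, 1.0, (4, 4, 8))
        sample = RadianceCube(values, grid8)
        illum = IlluminantCube(values.copy(), grid8)
        assert np.allclose(compute_reflectance(sample, illum).values, 1.0)

    def test_zero_sample_gives_zero_reflectance(self, grid8, rng):
        sample = RadianceCube(np.zeros((4, 4, 8)), grid8)
        illum = IlluminantCube(rng.uniform(0.1, 1, (4, 4, 8)), grid8)
        assert np.all(compute_reflectance(sample, illum).values == 0)

    def test_forward_inverse_round_trip(self, random_scene):
        reflectance, illum, _ = random_scene
        radiance = make_radiance(reflectance, illum)
        cube = IlluminantCube.broadcast(illum, *reflectance.shape[:2])
        recovered = compute_reflectance(radiance, cube)
        err = np.abs(recovered.values - reflectance.values)
        rel = err / np.maximum(reflectance.values, 1e-12)
        assert rel.max() <= 1e-10

    def test_clamped_bands_are_masked_not_divided(self, grid8):
        illum_values = np.full((2, 2, 8), 0.5)
        illum_values[..., 3] = 0.0  # dead band
        sample = RadianceCube(np.full((2, 2, 8), 0.25), grid8)
        cube, mask = compute_reflectance(
            sample, IlluminantCube(illum_values, grid8), floor=1e-6,
            return_mask=True,
        )
        assert np.all(np.isfinite(cube.values))
        assert mask[..., 3].all() and not mask[..., :3].any()

    def test_rejects_nonpositive_floor(self, grid8):
        sample = RadianceCube(np.ones((2, 2, 8)), grid8)
        illum = IlluminantCube(np.ones((2, 2, 8)), grid8)
        with pytest.raises(ValueError, match="floor"):
            compute_reflectance(sample, illum, floor=0.0)


class TestNormalizeUnitMax:
    def test_divides_by_maximum(self, grid8):
        image = RGBImage(np.array([[[1.0, 2.0, 4.0]]]))
        out = normalize_unit_max(image)
        assert np.allclose(out.values, [[[0.25, 0.5, 1.0]]])

    def test_idempotent_and_scale_invariant(self, grid8, rng):
        values = rng.uniform(0.1, 3.0, (4, 4, 8))
        cube = ReflectanceCube(values, grid8)
        once = normalize_unit_max(cube)
        assert np.allclose(normalize_unit_max(once).values, once.values)
        scaled = normalize_unit_max(ReflectanceCube(7.5 * values, grid8))
        assert np.allclose(scaled.values, once.values)

    def test_constant_image_becomes_all_ones(self):
        image = RGBImage(np.full((3, 3, 3), 0.4))
        assert np.all(normalize_unit_max(image).values == 1.0)

    def test_all_zero_input_is_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_unit_max(RGBImage(np.zeros((2, 2, 3))))


class TestResample:
    def test_linear_interpolation_midpoints(self):
        coarse = WavelengthGrid(np.array([400.0, 500.0, 600.0]))
        fine = WavelengthGrid(np.array([450.0, 550.0]))
        spectrum = IlluminantSpectrum(np.array([0.0, 1.0, 0.5]), coarse)
        out = resample_spectrum(spectrum, fine)
        assert np.allclose(out.power, [0.5, 0.75])

    def test_many_band_source_onto_working_grid(self, rng):
        source = WavelengthGrid.uniform(398.0, 1003.0, 204)
        target = WavelengthGrid.default(32)
        cube = RadianceCube(rng.uniform(0, 1, (4, 4, 204)), source)
        out = resample_spectrum(cube, target)
        assert out.grid == target
        assert np.all(out.values >= 0)

    def test_disjoint_grids_rejected(self):
        low = WavelengthGrid.uniform(400, 500, 4)
        high = WavelengthGrid.uniform(600, 700, 4)
        spectrum = IlluminantSpectrum(np.ones(4), low)
        with pytest.raises(ValueError, match="disjoint"):
            resample_spectrum(spectrum, high)


class TestPhysicsInvariants:
    def test_whiteboard_identity(self, rng):
        # imaging S≡1 equals imaging the broadcast illuminant, exactly
        grid = WavelengthGrid.default(16)
        for seed in range(20):
            local = np.random.default_rng(seed)
            illum = IlluminantSpectrum(local.uniform(0.05, 1, 16), grid)
            response = CameraResponse(local.uniform(0, 1, (3, 16)), grid)
            unit = ReflectanceCube(np.ones((5, 5, 16)), grid)
            lhs = render_rgb(make_radiance(unit, illum), response)
            rhs = render_rgb(IlluminantCube.broadcast(illum, 5, 5), response)
            assert np.array_equal(lhs.values, rhs.values)

    def test_render_is_linear(self, grid8):
        for seed in range(20):
            local = np.random.default_rng(seed)
            a, b = local.uniform(0.1, 3, 2)
            x = local.uniform(0, 1, (4, 4, 8))
            y = local.uniform(0, 1, (4, 4, 8))
            response = CameraResponse(local.uniform(0, 1, (3, 8)), grid8)
            combined = render_rgb(RadianceCube(a * x + b * y, grid8), response)
            parts = (a * render_rgb(RadianceCube(x, grid8), response).values
                     + b * render_rgb(RadianceCube(y, grid8), response).values)
            assert np.allclose(combined.values, parts, rtol=1e-12, atol=1e-12)


class TestPhysicsProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), scale=st.floats(0.01, 100.0))
    def test_normalize_is_scale_invariant(self, seed, scale):
        values = np.random.default_rng(seed).uniform(0.01, 1.0, (4, 4, 8))
        grid = WavelengthGrid.uniform(400.0, 700.0, 8)
        base = normalize_unit_max(ReflectanceCube(values, grid))
        scaled = normalize_unit_max(ReflectanceCube(scale * values, grid))
        assert np.allclose(base.values, scaled.values, rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_recovers_reflectance(self, seed):
        local = np.random.default_rng(seed)
        grid = WavelengthGrid.uniform(400.0, 700.0, 8)
        reflectance = ReflectanceCube(local.uniform(0, 1, (4, 4, 8)), grid)
        illum = IlluminantSpectrum(local.uniform(0.1, 1.0, 8), grid)
        recovered = compute_reflectance(
            make_radiance(reflectance, illum),
            IlluminantCube.broadcast(illum, 4, 4))
        assert np.allclose(recovered.values, reflectance.values,
                           rtol=1e-10, atol=1e-12)


class TestContainers:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([500.0, 400.0]))  # not increasing
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([100.0, 500.0]))  # out of range
        with pytest.raises(ValueError):
            WavelengthGrid(np.array([500.0]))  # too few bands

    def test_cube_validation(self, grid8):
        with pytest.raises(ValueError, match="negative"):
            ReflectanceCube(-np.ones((2, 2, 8)), grid8)
        with pytest.raises(ValueError, match="finite"):
            RadianceCube(np.full((2, 2, 8), np.nan), grid8)
        with pytest.raises(ValueError, match="bands"):
            RadianceCube(np.ones((2, 2, 7)), grid8)

    def test_illuminant_needs_positive_band(self, grid8):
        with pytest.raises(ValueError, match="positive"):
            IlluminantSpectrum(np.zeros(8), grid8)
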