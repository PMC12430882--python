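"""The LED bank, lighting conditions and the paired-scene generator."""

import numpy as np
import pytest

from specrec import (CameraResponse, SceneParams, WavelengthGrid, augment,
                     build_dataset, builtin_conditions, builtin_led_bank,
                     render_pair, sample_reflectance_field)
from specrec.synthetic import (_rotate, _shift, condition_spectrum,
                               split_sizes)

GRID = WavelengthGrid.default(32)


class TestLEDBank:
    def test_sixteen_leds_with_expected_classes(self):
        bank = builtin_led_bank()
        assert len(bank) == 16
        assert [led.id for led in bank] == list(range(1, 17))
        kinds = {led.id: led.kind for led in bank}
        assert all(kinds[i] == "warm_white" for i in (6, 11, 16))
        assert all(kinds[i] == "neutral_white" for i in (7, 10, 13))
        assert all(kinds[i] == "cool_white" for i in (1, 4))
        assert sum(k == "monochromatic" for k in kinds.values()) == 8

    def test_spectra_nonnegative_on_working_grid(self):
        for led in builtin_led_bank():
            assert np.all(led.spectrum(GRID).power >= 0)

    def test_warm_whites_redder_than_cool_whites(self):
        # energy ratio above/below 550 nm, integrated on the working grid
        bank = {led.id: led for led in builtin_led_bank()}
        long_mask = GRID.band_centers > 550

        def ratio(led_id: int) -> float:
            power = bank[led_id].spectrum(GRID).power
            return power[long_mask].sum() / power[~long_mask].sum()

        for warm in (6, 11, 16):
            for cool in (1, 4):
                assert ratio(warm) > ratio(cool)


class TestConditions:
    def test_sixteen_conditions_by_category(self):
        conditions = builtin_conditions()
        assert len(conditions) == 16
        sizes = [len(c.members) for c in conditions]
        assert sizes.count(1) == 8  # single whites
        assert sizes.count(2) == 5  # binary white mixes
        assert sizes.count(3) == 2  # tricolor mixes
        assert sizes.count(11) == 1  # multicolor mix

    def test_eleven_led_mix_membership(self):
        multi = [c for c in builtin_conditions() if len(c.members) == 11]
        assert len(multi) == 1
        ids = sorted(i for i, _ in multi[0].members)
        assert ids == [1, 2, 3, 5, 6, 7, 8, 9, 12, 14, 15]

    def test_all_conditions_strictly_positive_power(self):
        for condition in builtin_conditions():
            power = condition_spectrum(condition, GRID).power
            assert power.sum() > 0
            assert power.max() > 0.1  # meaningful light, not numerical dust


class TestReflectanceField:
    def test_deterministic_in_seed(self):
        params = SceneParams(image_size=16, n_bands=8)
        a = sample_reflectance_field(params, 7)
        b = sample_reflectance_field(params, 7)
        assert np.array_equal(a.values, b.values)
        c = sample_reflectance_field(params, 8)
        assert not np.array_equal(a.values, c.values)

    def test_background_dark_and_smooth_but_tinted(self):
        params = SceneParams(image_size=32, n_bands=16, n_blobs=1)
        cube = sample_reflectance_field(params, 3).values
        corner = cube[0, 0]  # blobs are centred; corners are background
        assert corner.mean() < 0.3
        assert np.abs(np.diff(corner, n=2)).max() < 0.05

    def test_values_in_range(self):
        params = SceneParams(image_size=24, n_bands=12)
        for seed in range(5):
            values = sample_reflectance_field(params, seed).values
            assert values.min() >= 0.0 and values.max() <= 1.2

    def test_spectra_have_bounded_curvature(self):
        # threshold frozen from a 20-scene batch on the default grid
        # (measured max |Δ²S| = 0.033)
        params = SceneParams()
        worst = max(
            np.abs(np.diff(sample_reflectance_field(params, s).values,
                           n=2, axis=2)).max()
            for s in range(10)
        )
        assert worst < 0.05


class TestRenderPair:
    params = SceneParams(image_size=16, n_bands=8, noise_sigma=0.0)

    def _pair(self, noise=0.0, seed=0):
        reflectance = sample_reflectance_field(self.params, 11)
        condition = builtin_conditions()[2]
        response = CameraResponse.gaussian(self.params.grid)
        return render_pair(reflectance, condition, response,
                           noise_sigma=noise, seed=seed)

    def test_noise_free_pair_is_exactly_consistent(self):
        self._pair().validate(atol=1e-12)

    def test_unit_reflectance_makes_sample_equal_light(self):
        from specrec import ReflectanceCube

        unit = ReflectanceCube(np.ones((16, 16, 8)), self.params.grid)
        pair = render_pair(unit, builtin_conditions()[0],
                           CameraResponse.gaussian(self.params.grid))
        assert np.allclose(pair.sample_rgb.values, pair.light_rgb.values)
        assert np.allclose(pair.reflectance_gt.values, 1.0)

    def test_noise_mean_matches_half_normal(self):
        # E|N(0,σ)| = σ·√(2/π); use a bright unit scene so the clip at zero
        # is negligible
        from specrec import ReflectanceCube

        params = SceneParams(image_size=64, n_bands=8)
        unit = ReflectanceCube(np.ones((64, 64, 8)), params.grid)
        condition = builtin_conditions()[0]
        response = CameraResponse.gaussian(params.grid)
        clean = render_pair(unit, condition, response, noise_sigma=0.0)
        sigma = 0.01
        perturbations = []
        for seed in range(30):
            noisy = render_pair(unit, condition, response,
                                noise_sigma=sigma, seed=seed)
            perturbations.append(
                np.abs(noisy.sample_rgb.values - clean.sample_rgb.values)
            )
        scale = clean.light_rgb.values.max()
        expected = sigma * scale * np.sqrt(2 / np.pi)
        measured = np.mean(perturbations)
        assert abs(measured - expected) / expected < 0.05

    def test_noisy_pair_keeps_ground_truth_clean(self):
        noisy = self._pair(noise=0.05, seed=1)
        clean = self._pair(noise=0.0)
        assert np.array_equal(noisy.reflectance_gt.values,
                              clean.reflectance_gt.values)
        assert not np.array_equal(noisy.sample_rgb.values,
                                  clean.sample_rgb.values)


class TestAugment:
    def _pair(self):
        params = SceneParams(image_size=16, n_bands=8)
        reflectance = sample_reflectance_field(params, 5)
        return render_pair(reflectance, builtin_conditions()[1],
                           CameraResponse.gaussian(params.grid))

    def test_empty_ops_returns_input_unchanged(self):
        pair = self._pair()
        assert augment(pair, [], seed=0) is pair

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            augment(self._pair(), ["zoom"], seed=0)

    def test_half_turn_rotation_is_involution(self, rng):
        arr = rng.random((8, 8, 4))
        assert np.array_equal(_rotate(_rotate(arr, 2), 2), arr)

    def test_shift_index_oracle(self, rng):
        arr = rng.random((12, 12, 3))
        out = _shift(arr, 0, 5)
        assert np.array_equal(out[:, 5:], arr[:, :-5])
        assert np.all(out[:, :5] == 0)

    def test_joint_transform_preserves_consistency(self):
        # the same geometry hits sample cube and ground truth; light untouched
        pair = self._pair()
        for seed in range(4):
            out = augment(pair, ["rotate", "shift"], seed=seed)
            assert out.sample_rgb.values.shape == pair.sample_rgb.values.shape
            assert out.light_rgb is pair.light_rgb
            assert out.light_hsi is pair.light_hsi
            out.validate(atol=1e-9)


class TestBuildDataset:
    def test_one_pair_per_condition_round_robin(self):
        params = SceneParams(image_size=8, n_bands=8)
        pairs, manifest = build_dataset(16, params=params, seed=0)
        names = [record["condition"] for record in manifest]
        assert len(set(names)) == 16

    def test_full_scale_preset_shapes(self):
        # the full campaign: 4000 pairs of 64×64 scenes with 32 bands; spot
        # check the first pair's shapes without generating all 4000
        params = SceneParams()
        assert (params.image_size, params.n_bands) == (64, 32)
        pairs, _ = build_dataset(1, params=params, seed=0)
        assert pairs[0].sample_rgb.values.shape == (64, 64, 3)
        assert pairs[0].sample_hsi.values.shape == (64, 64, 32)

    def test_split_protocol(self):
        assert split_sizes(3400) == (3000, 300, 100)
        train, val, test = split_sizes(128)
        assert (train + val + test) == 128 and min(train, val, test) >= 1

    def test_bit_reproducible(self):
        params = SceneParams(image_size=8, n_bands=8)
        a, ma = build_dataset(6, params=params, seed=42)
        b, mb = build_dataset(6, params=params, seed=42)
        assert ma == mb
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.sample_rgb.values, pb.sample_rgb.values)
            assert np.array_equal(pa.reflectance_gt.values,
                                  pb.reflectance_gt.values)

    def test_emitted_pairs_satisfy_invariants(self):
        params = SceneParams(image_size=8, n_bands=8)
        pairs, manifest = build_dataset(8, params=params, seed=9)
        for pair, record in zip(pairs, manifest):
            pair.validate(atol=1e-9)
            assert record["split"] in ("train", "val", "test")

    def test_reflectance_independent_of_condition(self):
        params = SceneParams(image_size=8, n_bands=8, noise_sigma=0.0)
        reflectance = sample_reflectance_field(params, 77)
        response = CameraResponse.gaussian(params.grid)
        conditions = builtin_conditions()
        a = render_pair(reflectance, conditions[0], response)
        b = render_pair(reflectance, conditions[7], response)
        assert np.allclose(a.reflectance_gt.values, b.reflectance_gt.values,
                           atol=1e-10)
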