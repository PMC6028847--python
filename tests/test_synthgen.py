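"""Phantom rasterisation, signal synthesis, noise model and bias-field tests."""

import numpy as np
import pytest

from dwiqc import (BiasField, Cylinder, GridSpec, PhantomScene, Sphere,
                   add_rician_noise, default_bias_field, fit_bias_field,
                   rasterize_scene, synthesize_dwi)
from dwiqc.exceptions import GeometryError, ValidationError
from dwiqc.synth import noiseless_signal


def brute_force_fractions(grid, sphere, ss):
    """Independent oracle: per-voxel inside fraction by explicit subvoxel loops."""
    out = np.zeros(grid.shape)
    r2 = (sphere.diameter_mm / 2.0) ** 2
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                count = 0
                for si in range(ss):
                    for sj in range(ss):
                        for sk in range(ss):
                            x = grid.origin[0] + (i + (si + 0.5) / ss) * grid.spacing[0]
                            y = grid.origin[1] + (j + (sj + 0.5) / ss) * grid.spacing[1]
                            z = grid.origin[2] + (k + (sk + 0.5) / ss) * grid.spacing[2]
                            d2 = ((x - sphere.center[0]) ** 2
                                  + (y - sphere.center[1]) ** 2
                                  + (z - sphere.center[2]) ** 2)
                            if d2 < r2:
                                count += 1
                out[i, j, k] = count / ss ** 3
    return out


class TestRasterize:
    def test_sphere_covering_one_voxel(self, small_grid):
        sphere = Sphere(center=(0.0, 0.0, 0.0), diameter_mm=2.0, adc=1e-3, s0=100.0)
        scene = PhantomScene((sphere,), background_s0=10.0,
                             background_adc=3e-4, grid=small_grid)
        raster = rasterize_scene(scene, supersample=1)
        frac = raster.fractions[0]
        center = tuple(s // 2 for s in small_grid.shape)
        assert frac[center] == 1.0
        assert frac.sum() == 1.0  # all other voxels are pure background

    def test_fractions_match_bruteforce_oracle(self):
        grid = GridSpec.centered((8, 8, 4), (2.0, 2.0, 5.0))
        sphere = Sphere(center=(1.3, -0.7, 2.1), diameter_mm=10.0,
                        adc=2e-3, s0=1000.0)
        scene = PhantomScene((sphere,), background_s0=0.0,
                             background_adc=0.0, grid=grid)
        raster = rasterize_scene(scene, supersample=5)
        oracle = brute_force_fractions(grid, sphere, 5)
        np.testing.assert_allclose(raster.fractions[0], oracle, atol=1e-12)

    def test_empty_scene_is_pure_background(self, small_grid):
        scene = PhantomScene((), background_s0=42.0, background_adc=7e-4,
                             grid=small_grid)
        raster = rasterize_scene(scene, supersample=2)
        np.testing.assert_array_equal(raster.s0_map, 42.0)
        np.testing.assert_array_equal(raster.adc_map, 7e-4)

    def test_overlapping_primitives_rejected(self, small_grid):
        a = Sphere(center=(0, 0, 0), diameter_mm=6.0, adc=1e-3, s0=1.0)
        b = Sphere(center=(2.0, 0, 0), diameter_mm=6.0, adc=1e-3, s0=1.0)
        scene = PhantomScene((a, b), background_s0=0.0, background_adc=0.0,
                             grid=small_grid)
        with pytest.raises(GeometryError):
            rasterize_scene(scene, supersample=2)

    def test_fractions_sum_to_one(self, small_grid):
        scene = PhantomScene(
            (Sphere(center=(0, 0, 0), diameter_mm=5.0, adc=1e-3, s0=1.0),),
            background_s0=0.5, background_adc=2e-4, grid=small_grid)
        raster = rasterize_scene(scene, supersample=3)
        np.testing.assert_allclose(raster.fractions.sum(axis=0), 1.0, atol=1e-15)


class TestSynthesize:
    @pytest.fixture()
    def water_voxel(self, small_grid):
        # grid fully inside a big water cylinder -> every voxel is pure water
        cyl = Cylinder(center=(0, 0, 0), diameter_mm=100.0, length_mm=100.0,
                       adc=1.1e-3, s0=1000.0)
        scene = PhantomScene((cyl,), background_s0=0.0, background_adc=0.0,
                             grid=small_grid)
        return rasterize_scene(scene, supersample=1)

    def test_closed_form_decay(self, water_voxel):
        sig = noiseless_signal(water_voxel, (0.0, 800.0))
        np.testing.assert_allclose(sig[..., 1], 1000.0 * np.exp(-0.88),
                                   rtol=1e-14)
        assert sig[0, 0, 0, 1] == pytest.approx(414.783, abs=5e-4)

    def test_b0_equals_s0(self, water_voxel):
        series = synthesize_dwi(water_voxel, (0.0, 500.0), noise_sd=0.0)[0]
        np.testing.assert_array_equal(series.volume(0.0), water_voxel.s0_map)

    def test_same_seed_bit_identical(self, water_voxel):
        a = synthesize_dwi(water_voxel, (0.0, 800.0), noise_sd=30.0,
                           n_repeats=2, seed=7)
        b = synthesize_dwi(water_voxel, (0.0, 800.0), noise_sd=30.0,
                           n_repeats=2, seed=7)
        c = synthesize_dwi(water_voxel, (0.0, 800.0), noise_sd=30.0,
                           n_repeats=2, seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)
        assert not np.array_equal(a[0].data, c[0].data)
        # repeats differ only by noise realisation
        assert not np.array_equal(a[0].data, a[1].data)

    def test_negative_b_rejected(self, water_voxel):
        with pytest.raises(ValidationError):
            synthesize_dwi(water_voxel, (-10.0, 800.0))

    def test_nonmonotone_b_rejected(self, water_voxel):
        with pytest.raises(ValidationError):
            synthesize_dwi(water_voxel, (0.0, 800.0, 100.0))


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        v = np.linspace(0, 10, 25).reshape(5, 5)
        out = add_rician_noise(v, 0.0, seed=0)
        np.testing.assert_array_equal(out, v)

    def test_zero_signal_gives_rayleigh_mean(self):
        out = add_rician_noise(np.zeros(200_000), 1.0, seed=3)
        # Rayleigh mean sqrt(pi/2); SD sqrt((4-pi)/2) -> 3 SE window
        se = np.sqrt((4 - np.pi) / 2) / np.sqrt(out.size)
        assert abs(out.mean() - np.sqrt(np.pi / 2)) < 3 * se

    def test_high_snr_limit(self):
        v = 100.0
        out = add_rician_noise(np.full(1_000_000, v), 1.0, seed=4)
        assert 1.0 <= out.mean() / v <= 1.0001

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            add_rician_noise(np.ones(3), -1.0)


class TestBiasField:
    def test_all_zero_profile_is_zero_field(self):
        field = fit_bias_field({"y": ((0.0, 2.0, 4.0), (0.0, 0.0, 0.0))})
        y = np.linspace(-80, 80, 9)
        np.testing.assert_allclose(field.evaluate(0.0, y, 0.0), 0.0, atol=1e-15)

    def test_exact_quadratic_interpolation(self):
        field = fit_bias_field({"y": ((0.0, 2.0, 4.0), (0.0, 4.0, 16.0))})
        # eps(y) = 0.01 * y_cm^2 exactly
        for y_cm in (1.0, 3.0, 7.0):
            assert field.evaluate(0.0, 10 * y_cm, 0.0) == pytest.approx(
                0.01 * y_cm ** 2, abs=1e-12)

    def test_default_field_zero_at_isocentre(self):
        assert default_bias_field().evaluate(0.0, 0.0, 0.0) == 0.0

    def test_default_field_tracks_its_profile(self):
        # quadratic least squares, not interpolation: values approximate the
        # anchor profile but the isocentre is exact by construction
        field = default_bias_field()
        at_8cm = field.evaluate(0.0, 80.0, 0.0)
        assert at_8cm == pytest.approx(0.241, abs=0.04)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_bias_field({"y": ((0.0, 2.0), (0.0, 4.0))})

    def test_missing_zero_anchor_rejected(self):
        with pytest.raises(ValidationError):
            fit_bias_field({"y": ((1.0, 2.0, 4.0), (1.0, 4.0, 16.0))})
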