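"""Stain-vector geometry, Beer-Lambert unmixing and kernel estimation."""

import math

import numpy as np
import pytest

from stainquant import (
    StainVector,
    build_kernel,
    deconvolve,
    estimate_kernel,
    load_kernel,
    polar_to_vector,
    preset_kernel,
    save_kernel,
    to_optical_density,
    vector_to_polar,
)
from stainquant.deconvolution import make_collage, negative_pixel_count, od_to_intensity
from stainquant.synthetic import stain_collage_scenes


class TestPolarVectors:
    def test_pole_maps_to_blue_axis(self):
        np.testing.assert_allclose(polar_to_vector(0, 0), [0, 0, 1], atol=1e-12)

    def test_equatorial_diagonal(self):
        np.testing.assert_allclose(
            polar_to_vector(45, 90), [math.sqrt(2) / 2, math.sqrt(2) / 2, 0], atol=1e-12
        )

    def test_roundtrip_identity(self, rng):
        for _ in range(1000):
            az = rng.uniform(1, 89)
            inc = rng.uniform(1, 89)
            az2, inc2 = vector_to_polar(polar_to_vector(az, inc))
            assert abs(az - az2) < 1e-9 and abs(inc - inc2) < 1e-9

    def test_negative_octant_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            polar_to_vector(180, 45)


class TestOpticalDensity:
    def test_blank_pixel_no_dye(self):
        np.testing.assert_array_equal(to_optical_density(np.ones((2, 2))), 0.0)

    def test_log10_closed_form(self):
        np.testing.assert_allclose(to_optical_density(np.full((2, 2), 0.1)), 1.0)

    def test_roundtrip(self, rng):
        img = rng.uniform(1e-3, 1, (8, 8, 3))
        np.testing.assert_allclose(
            od_to_intensity(to_optical_density(img)), img, atol=1e-9
        )


class TestBuildKernel:
    def test_identity_stains_identity_inverse(self):
        stains = [
            StainVector.from_vector("R", (1, 0, 0)),
            StainVector.from_vector("G", (0, 1, 0)),
            StainVector.from_vector("B", (0, 0, 1)),
        ]
        k = build_kernel(stains)
        np.testing.assert_allclose(k.inverse, np.eye(3), atol=1e-12)

    def test_two_orthogonal_completed_by_cross_product(self):
        k = build_kernel(
            [StainVector.from_vector("R", (1, 0, 0)), StainVector.from_vector("G", (0, 1, 0))]
        )
        third = k.matrix[2]
        assert abs(np.linalg.norm(third) - 1) < 1e-12
        assert abs(third @ k.matrix[0]) < 1e-12
        assert abs(third @ k.matrix[1]) < 1e-12

    def test_random_triple_inverse(self, rng):
        for _ in range(20):
            stains = [
                StainVector.from_angles(f"s{i}", rng.uniform(5, 85), rng.uniform(5, 85))
                for i in range(3)
            ]
            try:
                k = build_kernel(stains)
            except ValueError:
                continue  # nearly collinear draw
            np.testing.assert_allclose(k.matrix @ k.inverse, np.eye(3), atol=1e-9)

    def test_collinear_rejected(self):
        a = StainVector.from_angles("a", 30, 40)
        b = StainVector.from_angles("b", 30.2, 40.2)
        with pytest.raises(ValueError, match="collinear"):
            build_kernel([a, b])


class TestDeconvolve:
    def test_known_mixture_recovered(self):
        k = preset_kernel("oilredo_hematoxylin")
        od = 0.7 * k.stains[0].od_vector + 0.3 * k.stains[1].od_vector
        img = od_to_intensity(np.broadcast_to(od, (4, 4, 3)))
        maps = deconvolve(img, k)
        np.testing.assert_allclose(maps[k.stains[0].name], 0.7, atol=1e-6)
        np.testing.assert_allclose(maps[k.stains[1].name], 0.3, atol=1e-6)
        np.testing.assert_allclose(maps["residual"], 0.0, atol=1e-6)

    def test_blank_white_image_zero_concentrations(self):
        k = preset_kernel("alcianblue_nfr")
        maps = deconvolve(np.ones((5, 5, 3)), k)
        np.testing.assert_allclose(maps.maps, 0.0, atol=1e-9)

    def test_compose_deconvolve_roundtrip_rmse(self, rng):
        k = preset_kernel("alcianblue_nfr")
        c = rng.uniform(0, 0.8, (16, 16, 2))
        vectors = np.vstack([s.od_vector for s in k.stains])
        img = od_to_intensity(c @ vectors)
        maps = deconvolve(img, k)
        rmse = np.sqrt(np.mean((maps.maps[..., :2] - c) ** 2))
        assert rmse <= 1e-6

    def test_unmixing_is_linear_before_clipping(self, rng):
        k = preset_kernel("oilredo_hematoxylin")
        od1 = rng.uniform(0, 1, (6, 6, 3))
        od2 = rng.uniform(0, 1, (6, 6, 3))
        a, b = 0.6, 0.3
        raw = lambda od: deconvolve(od_to_intensity(od), k).raw
        np.testing.assert_allclose(
            raw(a * od1 + b * od2), a * raw(od1) + b * raw(od2), atol=1e-9
        )


class TestEstimateKernel:
    def test_recovers_true_angles_noise_free(self):
        true = preset_kernel("oilredo_hematoxylin")
        images = stain_collage_scenes(true, seed=1)
        init = build_kernel([
            StainVector.from_angles(true.stains[0].name,
                                    true.stains[0].azimuth + 4,
                                    true.stains[0].inclination - 4),
            StainVector.from_angles(true.stains[1].name,
                                    true.stains[1].azimuth - 4,
                                    true.stains[1].inclination + 4),
        ])
        est, diag = estimate_kernel(images, init, seed=1)
        for s, t in zip(est.stains, true.stains):
            assert abs(s.azimuth - t.azimuth) <= 1.0
            assert abs(s.inclination - t.inclination) <= 1.0
        assert diag["final_objective"] <= diag["initial_objective"]

    def test_blank_collage_returns_initial(self):
        init = preset_kernel("alcianblue_nfr")
        est, diag = estimate_kernel([np.ones((64, 64, 3))] * 9, init, seed=0)
        for s, t in zip(est.stains, init.stains):
            assert s.azimuth == t.azimuth and s.inclination == t.inclination

    def test_estimate_beats_rotated_kernel_on_negativity(self):
        true = preset_kernel("oilredo_hematoxylin")
        images = stain_collage_scenes(true, seed=2)
        collage = make_collage(images, seed=2)
        init = build_kernel([
            StainVector.from_angles(true.stains[0].name,
                                    true.stains[0].azimuth + 3,
                                    true.stains[0].inclination - 3),
            StainVector.from_angles(true.stains[1].name,
                                    true.stains[1].azimuth - 3,
                                    true.stains[1].inclination + 3),
        ])
        est, _ = estimate_kernel(images, init, seed=2)
        rotated = build_kernel([
            StainVector.from_angles(true.stains[0].name,
                                    true.stains[0].azimuth - 15,
                                    true.stains[0].inclination),
            StainVector.from_angles(true.stains[1].name,
                                    true.stains[1].azimuth - 15,
                                    true.stains[1].inclination),
        ])
        assert negative_pixel_count(collage, est) < negative_pixel_count(collage, rotated)

    def test_clipped_mass_fraction_small_with_true_kernel(self):
        true = preset_kernel("alcianblue_nfr")
        images = stain_collage_scenes(true, seed=3)
        collage = make_collage(images, seed=3)
        maps = deconvolve(collage, true)
        raw = maps.raw[..., :2]
        clipped_mass = -raw[raw < 0].sum()
        total_mass = np.abs(raw).sum()
        assert clipped_mass / total_mass < 1e-3


class TestKernelFiles:
    def test_yaml_roundtrip(self, tmp_path):
        k = preset_kernel("oilredo_hematoxylin")
        path = tmp_path / "kernel.yaml"
        save_kernel(k, path)
        k2 = load_kernel(path)
        np.testing.assert_allclose(k2.matrix, k.matrix, atol=1e-9)
        assert [s.name for s in k2.stains] == [s.name for s in k.stains]

    def test_presets_are_valid_kernels(self):
        for name in ("oilredo_hematoxylin", "alcianblue_nfr"):
            k = preset_kernel(name)
            assert k.n_stains == 2
            np.testing.assert_allclose(k.matrix @ k.inverse, np.eye(3), atol=1e-9)
            assert np.all(k.matrix[:2] >= 0)
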