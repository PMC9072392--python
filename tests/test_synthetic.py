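"""Generators: determinism, ground-truth consistency, angular law."""

import numpy as np
import pytest
from scipy import stats

from shgtex import (
    FiberSpec,
    generate_fiber_image,
    generate_ihc_image,
    generate_vessel_scene,
)


class TestFiberImage:
    def test_empty_scene_is_background_constant(self):
        img, truth = generate_fiber_image(
            shape_px=(64, 64), n_fibers=0, noise_model="none", background=7.0, seed=0
        )
        assert np.all(img.pixels == 7.0)
        assert truth.fibers == []

    def test_same_seed_bit_identical(self):
        a, _ = generate_fiber_image(shape_px=(64, 64), n_fibers=20, seed=11)
        b, _ = generate_fiber_image(shape_px=(64, 64), n_fibers=20, seed=11)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self):
        a, _ = generate_fiber_image(shape_px=(64, 64), n_fibers=20, seed=1)
        b, _ = generate_fiber_image(shape_px=(64, 64), n_fibers=20, seed=2)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_ground_truth_counts_fibers(self):
        _, truth = generate_fiber_image(shape_px=(64, 64), n_fibers=17, seed=0)
        assert len(truth.fibers) == 17
        assert truth.orientations_deg.shape == (17,)

    def test_zero_concentration_orientations_uniform(self):
        """With kappa = 0 the axial angles are uniform on [0, 180)."""
        _, truth = generate_fiber_image(
            shape_px=(64, 64), n_fibers=500, orientation_concentration=0.0, seed=42
        )
        counts, _ = np.histogram(truth.orientations_deg, bins=18, range=(0, 180))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_concentrated_orientations_near_mean(self):
        _, truth = generate_fiber_image(
            shape_px=(64, 64),
            n_fibers=200,
            orientation_mean_deg=45.0,
            orientation_concentration=30.0,
            seed=3,
        )
        dev = np.abs(truth.orientations_deg - 45.0)
        dev = np.minimum(dev, 180.0 - dev)
        assert np.percentile(dev, 90) < 20.0

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"shape_px": (16, 64)}, "shape_px"),
            ({"n_fibers": -1}, "n_fibers"),
            ({"orientation_concentration": -0.5}, "orientation_concentration"),
            ({"noise_model": "salt"}, "noise_model"),
            ({"pixel_size_um": 0.0}, "pixel_size_um"),
        ],
    )
    def test_invalid_parameters_rejected_by_name(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            generate_fiber_image(seed=0, **kwargs)

    def test_noise_models_nonnegative(self):
        for model in ("none", "gaussian", ("gaussian", 2.0), "poisson"):
            img, _ = generate_fiber_image(
                shape_px=(64, 64), n_fibers=5, noise_model=model, seed=0
            )
            assert np.all(img.pixels >= 0)

    def test_fiberspec_invariants(self):
        with pytest.raises(ValueError):
            FiberSpec((0, 0), 180.0, 10, 2, 1.0)
        with pytest.raises(ValueError):
            FiberSpec((0, 0), 10.0, 0.5, 2, 1.0)


class TestVesselScene:
    def test_same_seed_identical(self):
        a, _ = generate_vessel_scene(shape_px=(128, 128), vessel_radius_px=20,
                                     wall_thickness_px=6, seed=5)
        b, _ = generate_vessel_scene(shape_px=(128, 128), vessel_radius_px=20,
                                     wall_thickness_px=6, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_zero_wall_thickness_plain_disk_no_wall_fibers(self):
        img, truth = generate_vessel_scene(
            shape_px=(128, 128),
            vessel_radius_px=20,
            wall_thickness_px=0,
            collagen_params={"n_fibers": 10},
            seed=0,
        )
        assert len(truth.fibers) == 10  # background only
        mask = truth.vessel_mask
        rr, cc = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        disk = (rr - 63.5) ** 2 + (cc - 63.5) ** 2 <= 20**2
        assert np.array_equal(mask, disk)

    def test_wall_denser_than_parenchyma(self):
        """Perivascular collagen: wall annulus brighter than distant tissue."""
        img, truth = generate_vessel_scene(
            shape_px=(256, 256), vessel_radius_px=40, wall_thickness_px=12, seed=1
        )
        rr, cc = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
        rad = np.sqrt((rr - 127.5) ** 2 + (cc - 127.5) ** 2)
        wall = (rad > 40) & (rad <= 52)
        far = rad > 100
        assert img.pixels[wall].mean() / img.pixels[far].mean() > 1.0

    def test_vessel_mask_matches_image_shape(self):
        img, truth = generate_vessel_scene(shape_px=(96, 128), vessel_radius_px=15,
                                           wall_thickness_px=5, seed=0)
        assert truth.vessel_mask.shape == img.pixels.shape

    def test_oversized_vessel_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            generate_vessel_scene(shape_px=(64, 64), vessel_radius_px=40,
                                  wall_thickness_px=10, seed=0)


class TestIHCImage:
    @pytest.mark.parametrize("fraction, expected", [(0.0, 0), (1.0, 100 * 100)])
    def test_extreme_fractions(self, fraction, expected):
        _, truth = generate_ihc_image(
            shape_px=(100, 100), positive_fraction=fraction, seed=0
        )
        assert int(truth.positive_mask.sum()) == expected

    def test_exact_rounded_count(self):
        _, truth = generate_ihc_image(
            shape_px=(100, 100), positive_fraction=0.25, seed=1
        )
        assert int(truth.positive_mask.sum()) == 2500

    def test_same_seed_identical(self):
        a, _ = generate_ihc_image(shape_px=(64, 64), positive_fraction=0.3, seed=9)
        b, _ = generate_ihc_image(shape_px=(64, 64), positive_fraction=0.3, seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_rgb_uint8_output(self):
        img, _ = generate_ihc_image(shape_px=(32, 32), positive_fraction=0.5, seed=0)
        assert img.channel == "IHC_RGB"
        assert img.pixels.dtype == np.uint8
        assert img.pixels.shape == (32, 32, 3)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="positive_fraction"):
            generate_ihc_image(positive_fraction=1.2, seed=0)
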