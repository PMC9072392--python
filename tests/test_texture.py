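"""FOS and GLCM features against brute-force oracles and skimage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.feature import graycomatrix, graycoprops

from shgtex import compute_glcm, fos_features, sos_features
from shgtex.texture import GLCM, quantize


class TestFOS:
    def test_constant_image(self):
        f = fos_features(np.full((8, 8), 3.5))
        assert f.mean == 3.5 and f.std == 0.0
        assert math.isnan(f.skewness) and math.isnan(f.kurtosis)
        assert f.n_pixels == 64

    def test_two_point_symmetric_distribution(self):
        """Half 0s, half 2s: mean 1, std 1, skewness 0, kurtosis 1."""
        img = np.zeros((8, 8))
        img[:, 4:] = 2.0
        f = fos_features(img)
        assert f.mean == pytest.approx(1.0)
        assert f.std == pytest.approx(1.0)
        assert f.skewness == pytest.approx(0.0, abs=1e-12)
        assert f.kurtosis == pytest.approx(1.0)

    def test_matches_naive_oracle(self, naive_fos):
        rng = np.random.default_rng(7)
        for _ in range(20):
            img = rng.uniform(0, 255, size=(12, 12))
            f = fos_features(img)
            mu, std, skew, kurt = naive_fos(img)
            assert f.mean == pytest.approx(mu, abs=1e-10)
            assert f.std == pytest.approx(std, abs=1e-10)
            assert f.skewness == pytest.approx(skew, abs=1e-10)
            assert f.kurtosis == pytest.approx(kurt, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fos_features(np.empty((0, 0)))

    @given(
        hnp.arrays(
            np.float64,
            (6, 6),
            elements=st.floats(0, 1000, allow_nan=False),
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_kurtosis_at_least_one_when_defined(self, img):
        f = fos_features(img)
        if not math.isnan(f.kurtosis):
            assert f.kurtosis >= 1.0 - 1e-9


class TestGLCM:
    def test_constant_image_single_diagonal_entry(self):
        g = compute_glcm(np.full((16, 16), 5.0))
        assert g.p[0, 0] == pytest.approx(1.0)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_checkerboard_two_levels(self):
        """1-px checkerboard at distance 1, direction 0: all mass off-diagonal."""
        board = np.indices((8, 8)).sum(axis=0) % 2
        g = compute_glcm(board, n_levels=2, directions=(0.0,), symmetric=True)
        assert g.p[0, 1] == pytest.approx(0.5)
        assert g.p[1, 0] == pytest.approx(0.5)
        assert g.p[0, 0] == g.p[1, 1] == 0.0

    def test_normalization_across_seeds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = compute_glcm(rng.uniform(0, 1, size=(10, 10)), n_levels=8)
            assert abs(g.p.sum() - 1.0) < 1e-12

    def test_symmetric_flag_gives_symmetric_matrix(self):
        rng = np.random.default_rng(3)
        g = compute_glcm(rng.uniform(size=(16, 16)), n_levels=8, symmetric=True)
        assert np.allclose(g.p, g.p.T)

    def test_matches_naive_enumeration(self, naive_glcm):
        rng = np.random.default_rng(5)
        for _ in range(10):
            img = rng.uniform(0, 100, size=(9, 9))
            g = compute_glcm(img, n_levels=6)
            ref = naive_glcm(img, 6, 1, (0.0, 45.0, 90.0, 135.0), True)
            assert np.abs(g.p - ref).max() < 1e-12

    def test_matches_skimage_pooled_counts(self):
        """Pooled raw co-occurrence counts agree with skimage exactly."""
        rng = np.random.default_rng(11)
        img = rng.integers(0, 255, size=(32, 32)).astype(float)
        levels = quantize(img, 16).astype(np.uint8)
        g = compute_glcm(img, n_levels=16)
        sk = graycomatrix(
            levels, [1], np.deg2rad([0, 45, 90, 135]),
            levels=16, symmetric=True, normed=False,
        ).astype(float)
        pooled = sk[:, :, 0, :].sum(axis=2)
        pooled /= pooled.sum()
        assert np.abs(g.p - pooled).max() < 1e-15

    def test_image_smaller_than_offset_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.ones((1, 1)), distance_px=2, directions=(0.0,))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="n_levels"):
            compute_glcm(np.ones((4, 4)), n_levels=1)


class TestSOS:
    def test_diagonal_single_entry_fixed_points(self):
        g = compute_glcm(np.full((16, 16), 2.0))
        s = sos_features(g)
        assert s.energy == 1.0
        assert s.inertia == 0.0
        assert s.idm == 1.0
        assert s.entropy == 0.0
        assert s.correlation == 0.0  # zero-variance convention

    def test_checkerboard_features(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        s = sos_features(GLCM(p=p, n_levels=2, offsets=[(0, 1)], symmetric=True))
        assert s.energy == pytest.approx(0.5)
        assert s.entropy == pytest.approx(math.log(2.0))
        assert s.correlation == pytest.approx(-1.0)

    def test_matches_naive_oracle(self, naive_sos):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = compute_glcm(rng.uniform(0, 50, size=(10, 10)), n_levels=6)
            energy, inertia, corr, idm, entropy = naive_sos(g.p)
            s = sos_features(g)
            assert s.energy == pytest.approx(energy, abs=1e-12)
            assert s.inertia == pytest.approx(inertia, abs=1e-12)
            assert s.correlation == pytest.approx(corr, abs=1e-12)
            assert s.idm == pytest.approx(idm, abs=1e-12)
            assert s.entropy == pytest.approx(entropy, abs=1e-12)

    def test_matches_skimage_graycoprops(self):
        rng = np.random.default_rng(8)
        g = compute_glcm(rng.uniform(size=(24, 24)), n_levels=16)
        s = sos_features(g)
        p4 = g.p[:, :, None, None]
        assert s.inertia == pytest.approx(float(graycoprops(p4, "contrast")[0, 0]))
        assert s.idm == pytest.approx(float(graycoprops(p4, "homogeneity")[0, 0]))
        assert s.correlation == pytest.approx(
            float(graycoprops(p4, "correlation")[0, 0])
        )
        assert s.energy == pytest.approx(float(graycoprops(p4, "ASM")[0, 0]))
        assert s.entropy == pytest.approx(float(graycoprops(p4, "entropy")[0, 0]))

    def test_feature_ranges_on_random_images(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            s = sos_features(compute_glcm(rng.uniform(size=(16, 16)), n_levels=8))
            assert 0.0 < s.energy <= 1.0
            assert s.inertia >= 0.0
            assert -1.0 <= s.correlation <= 1.0
            assert 0.0 < s.idm <= 1.0
            assert s.entropy >= 0.0

    def test_intensity_shift_invariance(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 10, size=(20, 20))
        a = sos_features(compute_glcm(img))
        b = sos_features(compute_glcm(img + 123.0))
        assert a == b

    def test_energy_entropy_move_oppositely(self):
        """Interpolating a smooth image -> uniform noise: mean energy falls,
        mean entropy rises."""
        ts = [0.0, 0.25, 0.5, 0.75, 1.0]
        smooth = np.add.outer(np.arange(32), np.arange(32)).astype(float)
        energies, entropies = [], []
        for t in ts:
            es, hs = [], []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                noise = rng.uniform(0, 62, size=(32, 32))
                img = (1 - t) * smooth + t * noise
                s = sos_features(compute_glcm(img))
                es.append(s.energy)
                hs.append(s.entropy)
            energies.append(np.mean(es))
            entropies.append(np.mean(hs))
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(entropies, entropies[1:]))
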