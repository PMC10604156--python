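"""Metric definitions against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainrecon.data_model import ImageSet, ValidationError
from brainrecon.metrics import (
    RandomProjectionExtractor,
    evaluate_reconstructions,
    feature_distance,
    pixcorr,
    resize_to_common,
    ssim_global,
    ssim_windowed,
)


def _pearson_oracle(x, y):
    # independent textbook implementation: cov / (sd_x sd_y)
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return cov / (x.std() * y.std())


class TestPixCorr:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=(8, 8, 3))
        assert pixcorr(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        assert pixcorr([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_worked_example(self):
        assert pixcorr([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=50), rng.normal(size=50)
            assert abs(pixcorr(x, y) - _pearson_oracle(x, y)) <= 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            pixcorr(np.ones(5), np.arange(5.0))


class TestFeatureDistance:
    def test_zero_distance_to_self(self, rng):
        mu = rng.normal(size=32)
        assert feature_distance(mu, mu) == pytest.approx(0.0, abs=1e-12)

    def test_centered_antiparallel_is_two(self, rng):
        mu = rng.normal(size=16)
        assert feature_distance(mu, -mu + 3.7) == pytest.approx(2.0, abs=1e-10)

    def test_worked_example(self):
        assert feature_distance([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.2, abs=1e-12)

    def test_equals_one_minus_pearson(self, rng):
        for _ in range(100):
            mu, nu = rng.normal(size=40), rng.normal(size=40)
            assert abs(feature_distance(mu, nu) - (1 - _pearson_oracle(mu, nu))) <= 1e-10

    def test_agrees_with_pixcorr_on_vectors(self, rng):
        mu, nu = rng.normal(size=64), rng.normal(size=64)
        assert abs(pixcorr(mu, nu) - (1 - feature_distance(mu, nu))) <= 1e-10

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-20, 20), seed=st.integers(0, 10_000))
    def test_invariant_under_positive_affine_maps(self, a, b, seed):
        g = np.random.Generator(np.random.PCG64(seed))
        mu, nu = g.normal(size=12), g.normal(size=12)
        d0 = feature_distance(mu, nu)
        assert feature_distance(mu, a * nu + b) == pytest.approx(d0, abs=1e-8)
        assert feature_distance(nu, mu) == pytest.approx(d0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            feature_distance(np.ones(8), np.arange(8.0))


class TestSsim:
    def test_identical_images(self, rng):
        x = rng.random((16, 16, 3))
        assert ssim_global(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_closed_form(self):
        c1 = (0.01) ** 2
        for a in np.linspace(0.1, 1.0, 5):
            for b in np.linspace(0.1, 1.0, 5):
                x, y = np.full((8, 8), a), np.full((8, 8), b)
                expected = (2 * a * b + c1) / (a**2 + b**2 + c1)
                assert ssim_global(x, y) == pytest.approx(expected, abs=1e-12)

    def test_equal_constants_give_one(self):
        x = np.full((8, 8), 0.6)
        assert ssim_global(x, x.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_bounded_and_one_only_at_equality(self, rng):
        # SSIM lies in [-1, 1]; the covariance term can be negative
        for _ in range(20):
            x, y = rng.random((12, 12)), rng.random((12, 12))
            v = ssim_global(x, y)
            assert -1.0 <= v <= 1.0
            assert v < 1.0  # random pairs differ

    def test_windowed_mode_is_distinct_but_agrees_at_equality(self, rng):
        x = rng.random((32, 32))
        assert ssim_windowed(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValidationError):
            ssim_global(rng.random((4, 4)), rng.random((5, 5)))


def _bilinear_oracle(img, size):
    """Independent bilinear interpolation with half-pixel centers."""
    h, w = img.shape[:2]
    out = np.zeros((size, size) + img.shape[2:])
    for i in range(size):
        for j in range(size):
            y = (i + 0.5) * h / size - 0.5
            x = (j + 0.5) * w / size - 0.5
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            dy, dx = y - y0, x - x0
            ys = [min(max(y0, 0), h - 1), min(max(y0 + 1, 0), h - 1)]
            xs = [min(max(x0, 0), w - 1), min(max(x0 + 1, 0), w - 1)]
            out[i, j] = (
                img[ys[0], xs[0]] * (1 - dy) * (1 - dx)
                + img[ys[0], xs[1]] * (1 - dy) * dx
                + img[ys[1], xs[0]] * dy * (1 - dx)
                + img[ys[1], xs[1]] * dy * dx
            )
    return out


class TestResize:
    def test_identity_resize(self, rng):
        im = ImageSet([rng.random((16, 16, 3))], ["a"])
        out = resize_to_common(im, 16)
        assert np.array_equal(out.images[0], im.images[0])

    def test_constant_downscale(self):
        im = ImageSet([np.full((32, 32, 3), 0.25)], ["a"])
        out = resize_to_common(im, 16)
        assert np.allclose(out.images[0], 0.25)

    def test_checkerboard_matches_bilinear_oracle(self):
        board = np.indices((16, 16)).sum(axis=0) % 2
        img = np.repeat(board[..., None], 3, axis=2).astype(float)
        out = resize_to_common(ImageSet([img], ["a"]), 8).images[0]
        assert np.allclose(out, np.clip(_bilinear_oracle(img, 8), 0, 1), atol=1e-6)

    def test_minimum_size_enforced(self, rng):
        with pytest.raises(ValidationError):
            resize_to_common(ImageSet([rng.random((16, 16, 3))], ["a"]), 4)


class TestEvaluateReconstructions:
    @staticmethod
    def _images(rng, n, size=16):
        return ImageSet([rng.random((size, size, 3)) for _ in range(n)], [f"i{k}" for k in range(n)])

    def test_perfect_reconstruction(self, rng):
        truth = self._images(rng, 4)
        recon = ImageSet([im.copy() for im in truth.images], list(truth.image_ids))
        ext = RandomProjectionExtractor("proj", 32, seed=0)
        rep = evaluate_reconstructions(truth, recon, [ext], size=16)
        assert rep.aggregate["PixCorr"] == pytest.approx(1.0, abs=1e-10)
        assert rep.aggregate["SSIM"] == pytest.approx(1.0, abs=1e-10)
        assert rep.aggregate["projDist"] == pytest.approx(0.0, abs=1e-10)

    def test_independent_noise_has_null_pixcorr(self, rng):
        n, size = 24, 24
        truth = self._images(rng, n, size)
        recon = ImageSet([rng.random((size, size, 3)) for _ in range(n)], list(truth.image_ids))
        ext = RandomProjectionExtractor("proj", 16, seed=1)
        rep = evaluate_reconstructions(truth, recon, [ext], size=size)
        assert abs(rep.aggregate["PixCorr"]) < 3 / np.sqrt(size * size * 3 * n)

    def test_aggregate_is_column_mean(self, rng):
        truth = self._images(rng, 5)
        recon = self._images(np.random.Generator(np.random.PCG64(9)), 5)
        ext = RandomProjectionExtractor("proj", 16, seed=2)
        rep = evaluate_reconstructions(truth, recon, [ext], size=16)
        for col in rep.per_image.columns:
            assert rep.aggregate[col] == pytest.approx(rep.per_image[col].mean(), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        truth = self._images(rng, 6)
        recon = self._images(np.random.Generator(np.random.PCG64(4)), 6)
        ext = RandomProjectionExtractor("proj", 16, seed=3)
        rep = evaluate_reconstructions(truth, recon, [ext], size=16)
        perm = [3, 1, 5, 0, 2, 4]
        rep_p = evaluate_reconstructions(truth.subset(perm),
                                         recon.subset(perm), [ext], size=16)
        for col in rep.per_image.columns:
            assert rep_p.aggregate[col] == pytest.approx(rep.aggregate[col], abs=1e-12)
            assert np.allclose(
                rep_p.per_image[col].to_numpy(),
                rep.per_image[col].to_numpy()[perm],
            )

    def test_unpaired_ids_rejected(self, rng):
        truth = self._images(rng, 3)
        recon = ImageSet(truth.images[:2], ["i0", "i9"])
        with pytest.raises(ValidationError, match="unpaired|paired"):
            evaluate_reconstructions(truth, recon, [RandomProjectionExtractor("p", 8)], size=16)

    def test_extractor_determinism(self, rng):
        ext = RandomProjectionExtractor("proj", 24, seed=5)
        img = rng.random((20, 20, 3))
        assert np.array_equal(ext.extract(img), ext.extract(img))
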