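import numpy as np
import pytest

from catomo.errors import DomainError
from catomo.preprocess import (
    BackgroundModel,
    downsample_half,
    fit_background,
    remove_background,
    robust_stats,
)
from catomo.volume_io import BinaryMask, Volume3D


def full_mask(vol):
    return BinaryMask(data=np.ones(vol.shape, dtype=bool), voxel_size=vol.voxel_size)


class TestDownsample:
    def test_constant_preserved(self):
        vol = Volume3D(data=np.full((8, 8, 8), 4.2), voxel_size=1.0)
        out = downsample_half(vol)
        assert out.shape == (4, 4, 4)
        assert out.voxel_size == 2.0
        np.testing.assert_allclose(out.data, 4.2)

    def test_linear_ramp_gradient_preserved(self):
        # trilinear interpolation reproduces linear fields exactly; the
        # physical gradient (value per μm) must not change
        z, y, x = np.mgrid[0:16, 0:16, 0:16].astype(float)
        vol = Volume3D(data=3.0 * x, voxel_size=1.0)  # 3 units per μm
        out = downsample_half(vol)
        grad_per_um = np.diff(out.data, axis=2).mean() / out.voxel_size
        assert grad_per_um == pytest.approx(3.0, rel=1e-12)

    def test_commutes_with_constant_shift(self, rng):
        data = rng.normal(size=(12, 12, 12))
        vol = Volume3D(data=data, voxel_size=1.0)
        shifted = Volume3D(data=data + 17.0, voxel_size=1.0)
        np.testing.assert_allclose(
            downsample_half(shifted).data, downsample_half(vol).data + 17.0, atol=1e-10
        )

    def test_degenerate_axis_rejected(self):
        with pytest.raises(DomainError):
            downsample_half(Volume3D(data=np.zeros((1, 8, 8)), voxel_size=1.0))


class TestBackgroundFit:
    def test_exact_quadratic_recovered(self):
        y, x = np.mgrid[0:20, 0:24].astype(float)
        slice_ = 3.0 + 2.0 * x - y**2
        vol = Volume3D(data=np.stack([slice_] * 3), voxel_size=1.0)
        model = fit_background(vol)
        for coeffs in model.coefficients:
            np.testing.assert_allclose(coeffs, [3.0, 2.0, 0.0, 0.0, 0.0, -1.0], atol=1e-6)

    def test_constant_slices(self):
        vol = Volume3D(data=np.full((4, 10, 10), 5.0), voxel_size=1.0)
        model = fit_background(vol)
        np.testing.assert_allclose(model.coefficients[:, 0], 5.0, atol=1e-9)
        np.testing.assert_allclose(model.coefficients[:, 1:], 0.0, atol=1e-9)

    def test_noise_error_shrinks_as_sqrt_n(self, rng):
        # Monte-Carlo: coefficient error at n pixels scales ~ n^(-1/2)
        y16, x16 = np.mgrid[0:16, 0:16].astype(float)
        y64, x64 = np.mgrid[0:64, 0:64].astype(float)
        errs = {}
        for (y, x), key in [((y16, x16), 16), ((y64, x64), 64)]:
            truth = 1.0 + 0.5 * x + 0.2 * y
            trials = []
            for _ in range(20):
                noisy = truth + rng.normal(0, 1.0, size=truth.shape)
                vol = Volume3D(data=noisy[None], voxel_size=1.0)
                a = fit_background(vol).coefficients[0]
                trials.append(abs(a[0] - 1.0))
            errs[key] = np.mean(trials)
        # 16x more pixels => ~4x smaller error; allow a generous factor
        assert errs[64] < errs[16] / 2.0

    def test_sparse_slice_reuses_nearest_fit(self):
        data = np.zeros((3, 8, 8))
        data[0] = 7.0
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[0] = True  # only slice 0 can be fitted
        vol = Volume3D(data=data, voxel_size=1.0)
        model = fit_background(vol, BinaryMask(data=mask, voxel_size=1.0))
        np.testing.assert_allclose(model.coefficients[2], model.coefficients[0])

    def test_empty_mask_rejected(self):
        vol = Volume3D(data=np.zeros((2, 8, 8)), voxel_size=1.0)
        empty = BinaryMask(data=np.zeros((2, 8, 8), dtype=bool), voxel_size=1.0)
        with pytest.raises(DomainError):
            fit_background(vol, empty)


class TestRemoveBackground:
    def test_volume_equal_to_model_becomes_constant(self):
        y, x = np.mgrid[0:12, 0:12].astype(float)
        data = np.stack([1.0 + 0.3 * x + 0.1 * y * y for _ in range(4)])
        vol = Volume3D(data=data, voxel_size=1.0)
        out = remove_background(vol, fit_background(vol))
        np.testing.assert_allclose(out.data, data.mean(), atol=1e-8)

    def test_shading_free_volume_unchanged(self, rng):
        data = np.full((4, 16, 16), 50.0)
        vol = Volume3D(data=data, voxel_size=1.0)
        out = remove_background(vol, fit_background(vol))
        np.testing.assert_allclose(out.data, data, atol=1e-6)

    def test_shading_trend_reduced(self):
        from catomo.phantom import PhantomSpec, generate_phantom, make_shading

        shape = (32, 64, 64)
        spec = PhantomSpec(
            shape=shape,
            n_granules=0,
            noise_sd=2.0,
            shading_coefficients=make_shading(shape, amplitude=30.0, seed=3),
            seed=3,
        )
        vol, truth = generate_phantom(spec)

        def mean_abs_slope(v):
            # slope of the best linear fit along x, averaged over slices
            prof = v.data.mean(axis=1)  # (z, x)
            xs = np.arange(prof.shape[1])
            slopes = [np.polyfit(xs, p, 1)[0] for p in prof]
            return np.mean(np.abs(slopes))

        corrected = remove_background(vol, fit_background(vol))
        assert mean_abs_slope(corrected) <= 0.05 * mean_abs_slope(vol)

    def test_idempotent_within_tolerance(self, rng):
        y, x = np.mgrid[0:24, 0:24].astype(float)
        data = np.stack([10 + 0.4 * x - 0.05 * y**2 for _ in range(3)])
        vol = Volume3D(data=data, voxel_size=1.0)
        out = remove_background(vol, fit_background(vol))
        residual_coeffs = fit_background(out).coefficients
        np.testing.assert_allclose(residual_coeffs[:, 1:], 0.0, atol=1e-6)


class TestRobustStats:
    def test_gaussian_sample(self, rng):
        data = rng.normal(100.0, 5.0, size=(64, 64, 64))
        vol = Volume3D(data=data, voxel_size=1.0)
        mode, sd = robust_stats(vol, full_mask(vol))
        assert mode == pytest.approx(100.0, abs=1.0)
        assert sd == pytest.approx(5.0, abs=0.1)

    def test_delta_distribution(self):
        vol = Volume3D(data=np.full((8, 8, 8), 42.0), voxel_size=1.0)
        mode, sd = robust_stats(vol, full_mask(vol))
        assert mode == pytest.approx(42.0)
        assert sd == 0.0

    def test_bimodal_picks_taller_peak(self, rng):
        a = rng.normal(80.0, 2.0, size=40_000)
        b = rng.normal(120.0, 2.0, size=10_000)
        data = np.concatenate([a, b]).reshape(50, 50, 20)
        vol = Volume3D(data=data, voxel_size=1.0)
        mode, _ = robust_stats(vol, full_mask(vol))
        assert abs(mode - 80.0) < 2.0

    def test_empty_mask_rejected(self):
        vol = Volume3D(data=np.zeros((4, 4, 4)), voxel_size=1.0)
        with pytest.raises(DomainError):
            robust_stats(vol, BinaryMask(data=np.zeros((4, 4, 4), dtype=bool), voxel_size=1.0))


class TestDownscaledRecovery:
    def test_full_resolution_pipeline_recovers_granules(self):
        # 1 μm phantom -> half-resolution -> detection: >= 95% sensitivity for
        # granules >= 10 μm at 8 SD contrast, 1 SD noise; centroids within one
        # output voxel handled by the matching tolerance
        from catomo.granule_detect import detect
        from catomo.phantom import PhantomSpec, generate_phantom, match_catalog_to_truth

        spec = PhantomSpec(
            shape=(192, 192, 192),
            voxel_size=1.0,
            n_granules=30,
            diameter_log_mu=float(np.log(15.0)),
            diameter_log_sigma=0.2,
            diameter_range=(10.0, 30.0),
            granule_contrast=8.0,
            noise_sd=5.0,
            seed=21,
        )
        vol, truth = generate_phantom(spec)
        small = downsample_half(vol)
        corrected = remove_background(small, fit_background(small))
        catalog = detect(corrected)
        m = match_catalog_to_truth(catalog, truth)
        assert m["sensitivity"] >= 0.95
        assert m["n_false_positives"] == 0
        # detected centroids sit within one output voxel of the truth
        from scipy.spatial import cKDTree

        dists, _ = cKDTree(catalog.centroids).query(truth.centers)
        assert np.median(dists) <= small.voxel_size
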