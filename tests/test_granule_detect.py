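import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catomo.errors import DomainError
from catomo.granule_detect import (
    DetectionParams,
    Granule,
    GranuleCatalog,
    crofton_surface_area,
    detect,
    equivalent_spherical_diameter,
    filter_granules,
    hysteresis_mask,
    hysteresis_segment,
    measure_components,
    sphere_volume,
)
from catomo.volume_io import BinaryMask, Volume3D


def digitized_ball(d_voxels, pad=4):
    n = int(np.ceil(d_voxels)) + 2 * pad
    c = (n - 1) / 2
    z, y, x = np.mgrid[0:n, 0:n, 0:n]
    return np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= d_voxels / 2


def bfs_hysteresis_oracle(data, low, high):
    """Brute-force flood fill of the hysteresis rule (26-connected)."""
    from collections import deque

    low_mask = data > low
    out = np.zeros_like(low_mask)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    queue = deque(map(tuple, np.argwhere(data > high)))
    for p in queue:
        out[p] = True
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            q = (z + dz, y + dy, x + dx)
            if (
                0 <= q[0] < data.shape[0]
                and 0 <= q[1] < data.shape[1]
                and 0 <= q[2] < data.shape[2]
                and low_mask[q]
                and not out[q]
            ):
                out[q] = True
                queue.append(q)
    return out


class TestHysteresis:
    def test_constant_volume_has_no_components(self):
        vol = Volume3D(data=np.full((10, 10, 10), 100.0), voxel_size=1.0)
        labels = hysteresis_segment(vol, mode=100.0, sd=5.0)
        assert labels.max() == 0

    def test_skirt_joined_to_high_seed(self):
        data = np.full((12, 12, 12), 100.0)
        data[5:8, 5:8, 5:8] = 100 + 5 * 5.0  # skirt above low, below high
        data[6, 6, 6] = 100 + 8 * 5.0  # one high seed
        vol = Volume3D(data=data, voxel_size=1.0)
        labels = hysteresis_segment(vol, 100.0, 5.0)
        assert labels.max() == 1
        assert np.count_nonzero(labels) == 27  # the full skirt is included

    def test_blob_without_high_seed_dropped(self):
        data = np.full((12, 12, 12), 100.0)
        data[5:8, 5:8, 5:8] = 100 + 5 * 5.0  # never exceeds mode + 6 SD
        vol = Volume3D(data=data, voxel_size=1.0)
        assert hysteresis_segment(vol, 100.0, 5.0).max() == 0

    def test_matches_bfs_oracle_on_random_fields(self, rng):
        from scipy.ndimage import gaussian_filter

        for _ in range(10):
            data = gaussian_filter(rng.normal(size=(24, 24, 24)), 1.5)
            lo, hi = np.percentile(data, [88, 97])
            np.testing.assert_array_equal(
                hysteresis_mask(data, lo, hi), bfs_hysteresis_oracle(data, lo, hi)
            )

    def test_monotone_in_thresholds(self, rng):
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.normal(size=(24, 24, 24)), 1.2)
        lo, hi = np.percentile(data, [80, 95])
        base = hysteresis_mask(data, lo, hi).sum()
        assert hysteresis_mask(data, lo * 0.9 + hi * 0.1, hi).sum() <= base
        assert hysteresis_mask(data, lo, hi + 0.2 * abs(hi)).sum() <= base

    def test_nonpositive_sd_rejected(self):
        vol = Volume3D(data=np.zeros((4, 4, 4)), voxel_size=1.0)
        with pytest.raises(DomainError):
            hysteresis_segment(vol, 0.0, 0.0)


class TestMorphometry:
    @pytest.mark.parametrize("d", [10, 20, 30])
    def test_ball_sphericity_near_one(self, d):
        ball = digitized_ball(d)
        g = measure_components(ball.astype(np.int32), voxel_size=1.0)[0]
        assert 0.9 <= g.sphericity <= 1.05

    def test_cube_sphericity_below_ball(self):
        cube = np.zeros((28, 28, 28), dtype=np.int32)
        cube[4:24, 4:24, 4:24] = 1
        g = measure_components(cube, voxel_size=1.0)[0]
        ball = measure_components(digitized_ball(20).astype(np.int32), 1.0)[0]
        assert g.sphericity < ball.sphericity
        assert g.volume_um3 == 20**3

    def test_single_voxel_formulas(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        g = measure_components(labels, voxel_size=2.0)[0]
        assert g.volume_um3 == pytest.approx(8.0)
        assert g.diameter_um == pytest.approx((48 / np.pi) ** (1 / 3))
        assert g.centroid == pytest.approx((5.0, 5.0, 5.0))

    def test_centroid_respects_origin(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        g = measure_components(labels, voxel_size=2.0, origin=(100.0, 0.0, -10.0))[0]
        assert g.centroid == pytest.approx((105.0, 5.0, -5.0))

    def test_sphericity_scale_invariance(self):
        ball = digitized_ball(15).astype(np.int32)
        g1 = measure_components(ball, voxel_size=1.0)[0]
        g5 = measure_components(ball, voxel_size=5.0)[0]
        assert g1.sphericity == pytest.approx(g5.sphericity, rel=1e-12)
        assert g5.volume_um3 == pytest.approx(g1.volume_um3 * 125)
        assert g5.surface_um2 == pytest.approx(g1.surface_um2 * 25)

    def test_boundary_components_flagged(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[0:2, 2:4, 2:4] = 1
        labels[3:5, 2:4, 2:4] = 2
        granules = measure_components(labels, 1.0)
        assert granules[0].touches_boundary and not granules[1].touches_boundary

    def test_empty_labeling_gives_empty_list(self):
        assert measure_components(np.zeros((4, 4, 4), dtype=np.int32), 1.0) == []

    def test_crofton_on_ball_matches_analytic_surface(self):
        ball = digitized_ball(30)
        v = ball.sum()
        d_equiv = equivalent_spherical_diameter(v)
        assert crofton_surface_area(ball, 1.0) == pytest.approx(np.pi * d_equiv**2, rel=0.02)


class TestFilter:
    def _granule(self, volume, sphericity):
        return Granule(
            id=1,
            centroid=(0, 0, 0),
            voxel_count=0,
            volume_um3=volume,
            surface_um2=1.0,
            sphericity=sphericity,
            diameter_um=equivalent_spherical_diameter(volume),
        )

    def test_volume_threshold_is_strict(self):
        assert len(filter_granules([self._granule(365.0, 0.95)])) == 0
        assert len(filter_granules([self._granule(365.0001, 0.95)])) == 1

    def test_sphericity_threshold_is_strict(self):
        assert len(filter_granules([self._granule(400.0, 0.85)])) == 0
        assert len(filter_granules([self._granule(400.0, 0.851)])) == 1

    def test_minimum_admissible_diameter(self):
        # the volume cut of 365 μm³ maps to an 8.87 μm equivalent diameter
        assert round(equivalent_spherical_diameter(365.0), 2) == 8.87

    def test_provenance_recorded(self):
        cat = filter_granules([self._granule(400, 0.9)], DetectionParams())
        assert cat.provenance["min_volume_um3"] == 365.0
        assert cat.provenance["k_high"] == 6.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=1e6))
    def test_diameter_volume_round_trip(self, volume):
        assert sphere_volume(equivalent_spherical_diameter(volume)) == pytest.approx(
            volume, rel=1e-12
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            DetectionParams(k_high=4.0, k_low=4.5)
        with pytest.raises(DomainError):
            DetectionParams(min_sphericity=1.5)


class TestDetect:
    def test_phantom_recovery_no_false_positives(self):
        from catomo.phantom import PhantomSpec, generate_phantom, match_catalog_to_truth

        # well-separated: ~0.5% volume fraction so hysteresis skirts of
        # neighbouring granules cannot bridge
        spec = PhantomSpec(
            shape=(176, 176, 176),
            voxel_size=2.0,
            n_granules=50,
            diameter_log_mu=float(np.log(16.0)),
            diameter_log_sigma=0.15,
            diameter_range=(12.0, 30.0),
            noise_sd=5.0,
            seed=13,
        )
        vol, truth = generate_phantom(spec)
        catalog = detect(vol, truth.tissue_mask)
        m = match_catalog_to_truth(catalog, truth)
        assert m["sensitivity"] >= 48 / 50
        assert m["n_false_positives"] == 0

    def test_small_granules_fall_below_volume_filter(self):
        from catomo.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(
            shape=(96, 96, 96),
            voxel_size=2.0,
            n_granules=15,
            diameter_log_mu=float(np.log(6.0)),
            diameter_log_sigma=1e-9,
            diameter_range=(5.9, 6.1),
            noise_sd=5.0,
            seed=8,
        )
        vol, truth = generate_phantom(spec)
        assert not any(g.above_filter for g in truth.granules)
        assert len(detect(vol, truth.tissue_mask)) == 0

    def test_empty_mask_gives_empty_catalog(self):
        vol = Volume3D(data=np.zeros((8, 8, 8)), voxel_size=1.0)
        empty = BinaryMask(data=np.zeros((8, 8, 8), dtype=bool), voxel_size=1.0)
        assert len(detect(vol, empty)) == 0

    def test_catalog_csv_round_trip(self, tmp_path):
        from catomo.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(shape=(64, 64, 64), voxel_size=2.0, n_granules=5, seed=3)
        vol, truth = generate_phantom(spec)
        catalog = detect(vol, truth.tissue_mask)
        assert len(catalog) > 0
        path = tmp_path / "catalog.csv"
        catalog.to_csv(path)
        back = GranuleCatalog.from_csv(path)
        np.testing.assert_allclose(back.centroids, catalog.centroids)
        np.testing.assert_allclose(back.diameters, catalog.diameters)
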