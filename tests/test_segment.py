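"""Preprocessing and segmentation against brute-force oracles."""

import numpy as np
import pytest

from kinetocoloc import (
    ColocParams,
    VoxelGrid,
    gaussian_smooth,
    morphological_opening,
    otsu_threshold,
    reslice_isotropic,
    segment_spots,
)
from kinetocoloc.errors import DegenerateHistogramError, InvalidParameterError


def _split_icv(counts: np.ndarray, centers: np.ndarray, k: int) -> float:
    """Weighted intraclass variance of the split bins[:k] | bins[k:]."""
    w0, w1 = counts[:k].sum(), counts[k:].sum()
    if w0 == 0 or w1 == 0:
        return np.inf
    m0 = (counts[:k] * centers[:k]).sum() / w0
    m1 = (counts[k:] * centers[k:]).sum() / w1
    return float(
        (counts[:k] * (centers[:k] - m0) ** 2).sum()
        + (counts[k:] * (centers[k:] - m1) ** 2).sum()
    )


def _histogram(data: np.ndarray, n_bins: int = 256):
    flat = np.asarray(data, dtype=float).ravel()
    counts, edges = np.histogram(flat, bins=n_bins, range=(flat.min(), flat.max()))
    return counts, (edges[:-1] + edges[1:]) / 2.0


def brute_force_otsu(data: np.ndarray, n_bins: int = 256) -> tuple[float, float]:
    """Exhaustive intraclass-variance minimizer over every histogram split.

    Returns (threshold, minimal intraclass variance). The discrete Otsu
    objective can plateau over empty histogram bins, so thresholds should
    be compared by their achieved objective (see :func:`otsu_icv_of`).
    """
    counts, centers = _histogram(data, n_bins)
    best_thr, best_icv = None, np.inf
    for k in range(1, n_bins):
        icv = _split_icv(counts, centers, k)
        if icv < best_icv:
            best_icv, best_thr = icv, centers[k - 1]
    return best_thr, best_icv


def otsu_icv_of(data: np.ndarray, threshold: float, n_bins: int = 256) -> float:
    """Intraclass variance achieved by a given bin-center threshold."""
    counts, centers = _histogram(data, n_bins)
    k = int(np.argmin(np.abs(centers - threshold))) + 1
    return _split_icv(counts, centers, k)


def brute_force_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion then dilation with a (2r+1)-cube, via explicit shifts."""
    offsets = range(-radius, radius + 1)
    n = mask.shape

    def shifted(m, dz, dy, dx, fill):
        out = np.full(n, fill, dtype=bool)
        src = tuple(
            slice(max(0, -d), min(s, s - d)) for d, s in zip((dz, dy, dx), n)
        )
        dst = tuple(
            slice(max(0, d), min(s, s + d)) for d, s in zip((dz, dy, dx), n)
        )
        out[dst] = m[src]
        return out

    eroded = np.ones(n, dtype=bool)
    for dz in offsets:
        for dy in offsets:
            for dx in offsets:
                eroded &= shifted(mask, dz, dy, dx, fill=False)
    dilated = np.zeros(n, dtype=bool)
    for dz in offsets:
        for dy in offsets:
            for dx in offsets:
                dilated |= shifted(eroded, dz, dy, dx, fill=False)
    return dilated


def grid(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), spacing)


class TestReslice:
    def test_isotropic_input_is_identity(self, rng):
        g = grid(rng.random((6, 6, 6)))
        out = reslice_isotropic(g)
        np.testing.assert_array_equal(out.data, g.data)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_doubling_rule_node_aligned(self, rng):
        # dz = 2 dx with 11 slices: 2*(11-1)+1 = 21 output samples; even
        # samples hit input nodes, odd samples are midpoint averages
        data = rng.random((11, 5, 5))
        out = reslice_isotropic(grid(data, spacing=(0.5, 0.25, 0.25)))
        assert out.data.shape == (21, 5, 5)
        assert out.spacing == (0.25, 0.25, 0.25)
        np.testing.assert_allclose(out.data[::2], data, atol=1e-12)
        midpoints = (data[:-1] + data[1:]) / 2.0
        np.testing.assert_allclose(out.data[1::2], midpoints, atol=1e-12)

    def test_constant_grid_stays_constant(self):
        out = reslice_isotropic(grid(np.full((7, 8, 8), 3.5), spacing=(0.6, 0.2, 0.2)))
        np.testing.assert_allclose(out.data, 3.5)

    def test_physical_extent_preserved(self, rng):
        g = grid(rng.random((9, 6, 6)), spacing=(0.9, 0.3, 0.3))
        out = reslice_isotropic(g)
        in_extent = (9 - 1) * 0.9
        out_extent = (out.data.shape[0] - 1) * out.spacing[0]
        assert abs(out_extent - in_extent) <= 0.3  # within one voxel

    def test_single_slice_falls_back_to_nearest(self, rng):
        g = grid(rng.random((1, 4, 4)), spacing=(1.0, 0.5, 0.5))
        with pytest.warns(UserWarning, match="nearest"):
            out = reslice_isotropic(g, "linear")
        assert out.data.shape[0] == 1


class TestGaussianSmooth:
    def test_preserves_constants(self):
        out = gaussian_smooth(grid(np.full((9, 9, 9), 50.0)), 1.0)
        np.testing.assert_allclose(out.data, 50.0)

    def test_impulse_center_value(self):
        # 3D Gaussian kernel normalization: (2*pi)^(-3/2) for sigma = 1
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(grid(data), 1.0)
        expected = (2 * np.pi) ** -1.5
        assert out.data[10, 10, 10] == pytest.approx(expected, rel=0.05)

    def test_sigma_zero_is_identity(self, rng):
        g = grid(rng.random((5, 5, 5)))
        out = gaussian_smooth(g, 0.0)
        assert out.data.tobytes() == g.data.tobytes()

    def test_max_does_not_increase(self, rng):
        g = grid(rng.random((8, 8, 8)))
        assert gaussian_smooth(g, 1.5).data.max() <= g.data.max() + 1e-12

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            gaussian_smooth(grid(rng.random((4, 4, 4))), -1.0)


class TestOtsu:
    def test_two_level_volume_matches_brute_force(self):
        data = np.concatenate([np.full(900, 10.0), np.full(100, 200.0)])
        data = data.reshape(10, 10, 10)
        thr = otsu_threshold(grid(data))
        assert 10 < thr < 200
        # the two classes are fully separated either way
        _, best_icv = brute_force_otsu(data)
        assert otsu_icv_of(data, thr) == pytest.approx(best_icv)
        assert np.array_equal(data > thr, data >= 200)

    def test_random_volumes_match_brute_force(self, rng):
        # thresholds compared through the objective they achieve: the
        # discrete optimum can be a tie across empty histogram bins
        for _ in range(10):
            data = rng.random((16, 16, 16)) * rng.integers(1, 100)
            _, best_icv = brute_force_otsu(data)
            assert otsu_icv_of(data, otsu_threshold(data)) == pytest.approx(best_icv, rel=1e-9)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(grid(np.full((4, 4, 4), 42.0)))

    def test_threshold_strictly_inside_range(self, rng):
        data = rng.normal(100, 20, (12, 12, 12)).clip(0)
        thr = otsu_threshold(data)
        assert data.min() < thr < data.max()


class TestOpening:
    def test_isolated_voxel_removed(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        assert not morphological_opening(mask, 1).any()
        np.testing.assert_array_equal(
            morphological_opening(mask, 1), brute_force_opening(mask, 1)
        )

    def test_solid_cube_unchanged(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        np.testing.assert_array_equal(morphological_opening(mask, 1), mask)
        np.testing.assert_array_equal(brute_force_opening(mask, 1), mask)

    def test_radius_zero_is_identity(self, rng):
        mask = rng.random((6, 6, 6)) > 0.5
        np.testing.assert_array_equal(morphological_opening(mask, 0), mask)

    def test_properties_on_random_masks(self, rng):
        for _ in range(10):
            a = rng.random((8, 8, 8)) > 0.4
            opened = morphological_opening(a, 1)
            np.testing.assert_array_equal(opened, brute_force_opening(a, 1))
            assert not (opened & ~a).any()  # anti-extensive
            np.testing.assert_array_equal(morphological_opening(opened, 1), opened)  # idempotent
            b = a | (rng.random((8, 8, 8)) > 0.6)
            assert not (opened & ~morphological_opening(b, 1)).any()  # increasing


class TestSegmentSpots:
    def test_applied_threshold_is_scaled_otsu(self, rng):
        g = grid(rng.random((10, 10, 10)) * 100)
        seg = segment_spots(g, ColocParams(otsu_scale=1.08))
        assert seg.applied_threshold == pytest.approx(1.08 * seg.otsu_value)

    def test_scale_of_1_08_applied_to_100(self):
        # otsu_value 100 must give applied threshold 108
        data = np.concatenate([np.zeros(500), np.full(500, 200.0)]).reshape(10, 10, 10)
        seg = segment_spots(grid(data), ColocParams(otsu_scale=1.08))
        assert seg.applied_threshold == pytest.approx(1.08 * seg.otsu_value)
        assert np.isclose(seg.applied_threshold / seg.otsu_value, 1.08)

    def test_recovers_spot_count_on_noise_free_frame(self, small_movie, small_params):
        movie, _ = small_movie
        marker = reslice_isotropic(movie.grid(0, "MIS12"))
        seg = segment_spots(gaussian_smooth(marker, 1.0))
        assert seg.n_components == small_params.n_spots

    def test_uniform_rescaling_invariance(self, small_movie):
        movie, _ = small_movie
        marker = gaussian_smooth(reslice_isotropic(movie.grid(0, "MIS12")), 1.0)
        seg1 = segment_spots(marker)
        seg2 = segment_spots(marker.with_data(marker.data * 37.5))
        np.testing.assert_array_equal(seg1.mask, seg2.mask)
        assert seg1.n_components == seg2.n_components

    def test_all_below_threshold_warns_empty(self):
        data = np.concatenate([np.zeros(990), np.full(10, 10.0)]).reshape(10, 10, 10)
        # isolated bright voxels are opened away -> empty mask, warning
        rng = np.random.default_rng(0)
        data = np.zeros((10, 10, 10))
        idx = rng.choice(1000, size=5, replace=False)
        data.ravel()[idx] = 10.0
        with pytest.warns(UserWarning, match="empty segmentation"):
            seg = segment_spots(grid(data))
        assert seg.n_components == 0
        assert seg.n_voxels == 0
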