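"""Fixed-cell colocalization: projections, threshold sweep, profile overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinetocoloc import (
    IntensityProfile,
    Roi2D,
    auto_threshold_pair,
    coloc_percent_fixed,
    max_projection,
    profile_overlap_percent,
)
from kinetocoloc.errors import (
    InvalidParameterError,
    UndefinedOverlapError,
    UndefinedRegressionError,
)


def two_blob_image(overlap_cols: int, size: int = 32, blob: int = 8):
    """Channel a: one bright blob; channel b: a blob shifted so that
    `overlap_cols` of its columns coincide with a's blob."""
    a = np.zeros((size, size))
    b = np.zeros((size, size))
    r0 = size // 2 - blob // 2
    a[r0:r0 + blob, 4:4 + blob] = 100.0
    shift = blob - overlap_cols
    b[r0:r0 + blob, 4 + shift:4 + shift + blob] = 100.0
    return a, b


class TestMaxProjection:
    def test_single_slice_identity(self, rng):
        img = rng.random((1, 6, 7))
        np.testing.assert_array_equal(max_projection(img), img[0])

    def test_zero_slice_ignored(self, rng):
        sl = rng.random((5, 5))
        vol = np.stack([np.zeros((5, 5)), sl])
        np.testing.assert_array_equal(max_projection(vol), sl)

    def test_matches_elementwise_brute_force(self, rng):
        vol = rng.random((8, 8, 8))
        proj = max_projection(vol)
        for y in range(8):
            for x in range(8):
                assert proj[y, x] == max(vol[z, y, x] for z in range(8))


class TestAutoThresholdPair:
    def test_identical_channels_reach_floor_percent_100(self, rng):
        a = rng.random((16, 16)) * 100
        pair = auto_threshold_pair(a, a.copy())
        assert pair.at_floor
        assert pair.slope == pytest.approx(1.0)
        assert pair.intercept == pytest.approx(0.0, abs=1e-9)
        res = coloc_percent_fixed(a, a.copy())
        assert res.percent == pytest.approx(100.0)

    def test_disjoint_supports_percent_near_zero(self):
        a, b = two_blob_image(overlap_cols=0)
        res = coloc_percent_fixed(a, b)
        assert res.percent <= 5.0

    def test_deterministic(self, rng):
        a = rng.random((20, 20)) * 50
        b = 0.5 * a + rng.random((20, 20)) * 10
        p1 = auto_threshold_pair(a, b)
        p2 = auto_threshold_pair(a, b)
        assert (p1.threshold_a, p1.threshold_b) == (p2.threshold_a, p2.threshold_b)

    def test_zero_variance_channel_rejected(self, rng):
        a = rng.random((8, 8))
        with pytest.raises(UndefinedRegressionError):
            auto_threshold_pair(a, np.full((8, 8), 3.0))

    def test_sweep_equals_exhaustive_search(self, rng):
        """The downward sweep must return the highest candidate threshold
        whose below-threshold Pearson correlation is <= 0 (exhaustively
        checked over every candidate on a small image)."""
        a = rng.random((16, 16)) * 100
        b = -0.6 * a + 80 + rng.normal(0, 5, (16, 16))
        b -= b.min()
        pair = auto_threshold_pair(a, b, n_steps=64)
        slope, intercept = np.polyfit(a.ravel(), b.ravel(), 1)
        candidates = np.linspace(a.max(), a.min(), 65)[1:]
        winner = None
        for t in candidates:  # highest-first
            sel = (a.ravel() < t) & (b.ravel() < slope * t + intercept)
            xa, xb = a.ravel()[sel], b.ravel()[sel]
            if xa.size >= 2 and np.ptp(xa) > 0 and np.ptp(xb) > 0:
                r = np.corrcoef(xa, xb)[0, 1]
                if r <= 0:
                    winner = t
                    break
        assert winner is not None
        assert pair.threshold_a == pytest.approx(winner)


class TestColocPercent:
    def test_inverted_two_level_image_is_zero(self):
        a = np.zeros((16, 16))
        a[4:12, 4:12] = 100.0
        b = a.max() - a
        res = coloc_percent_fixed(a, b)
        assert res.percent == pytest.approx(0.0)

    def test_half_overlap_blob_near_fifty(self):
        a, b = two_blob_image(overlap_cols=4, blob=8)
        res = coloc_percent_fixed(a, b)
        assert res.percent == pytest.approx(50.0, abs=2.0)

    def test_monotone_in_overlap(self):
        percents = [coloc_percent_fixed(*two_blob_image(k)).percent for k in (0, 2, 4, 6, 8)]
        assert all(q >= p for p, q in zip(percents, percents[1:]))
        assert percents[0] <= 5 and percents[-1] >= 95

    def test_roi_restricts_computation(self):
        a, b = two_blob_image(overlap_cols=8)
        roi = Roi2D(origin=(12, 2), height=12, width=12, pixel_size=0.1)
        res = coloc_percent_fixed(a, b, roi)
        assert 0 <= res.percent <= 100

    def test_roi_total_denominator_not_larger(self):
        a, b = two_blob_image(overlap_cols=6)
        ref = coloc_percent_fixed(a, b, denominator="reference").percent
        tot = coloc_percent_fixed(a, b, denominator="roi_total").percent
        assert tot <= ref


class TestRoi2D:
    def test_area_from_pixel_size(self):
        roi = Roi2D(origin=(0, 0), height=10, width=20, pixel_size=0.1)
        assert roi.area == pytest.approx(10 * 20 * 0.01)

    def test_square_of_default_area(self):
        # 4.2 µm^2 at 0.1 µm pixels -> side ~ 20.5 pixels
        roi = Roi2D.square_of_area(pixel_size=0.1)
        assert roi.height == roi.width
        assert roi.area == pytest.approx(4.2, rel=0.1)

    def test_out_of_bounds_extraction_rejected(self):
        roi = Roi2D(origin=(5, 5), height=10, width=10)
        with pytest.raises(InvalidParameterError):
            roi.extract(np.zeros((8, 8)))


class TestProfileOverlap:
    @staticmethod
    def profile(values, length=6.0):
        values = np.asarray(values, dtype=float)
        pos = np.linspace(0, length, values.size)
        return IntensityProfile(positions=pos, values=values)

    def test_identical_profiles_give_100(self, rng):
        vals = rng.random(25) + 0.1
        a = self.profile(vals)
        b = self.profile(vals.copy())
        assert profile_overlap_percent(a, b) == pytest.approx(100.0)

    def test_disjoint_supports_give_0(self):
        a = self.profile([0, 1, 2, 1, 0, 0, 0, 0, 0])
        b = self.profile([0, 0, 0, 0, 0, 1, 2, 1, 0])
        assert profile_overlap_percent(a, b) == pytest.approx(0.0)

    def test_constant_2_vs_1_gives_50(self):
        a = self.profile(np.full(13, 2.0))
        b = self.profile(np.full(13, 1.0))
        assert profile_overlap_percent(a, b) == pytest.approx(50.0)

    def test_100_iff_b_covers_a(self, rng):
        vals = rng.random(20) + 0.05
        a = self.profile(vals)
        assert profile_overlap_percent(a, self.profile(vals + 0.2)) == pytest.approx(100.0)
        shaved = vals.copy()
        shaved[7] *= 0.5
        assert profile_overlap_percent(a, self.profile(shaved)) < 100.0

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_joint_rescaling_invariance(self, scale):
        vals_a = np.array([0.0, 1.0, 3.0, 2.0, 0.5, 0.0])
        vals_b = np.array([0.5, 2.0, 1.0, 2.5, 0.1, 0.0])
        base = profile_overlap_percent(self.profile(vals_a), self.profile(vals_b))
        scaled = profile_overlap_percent(
            self.profile(vals_a * scale), self.profile(vals_b * scale)
        )
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0 <= scaled <= 100

    def test_zero_reference_rejected(self):
        a = self.profile(np.zeros(8))
        b = self.profile(np.ones(8))
        with pytest.raises(UndefinedOverlapError):
            profile_overlap_percent(a, b)

    def test_mismatched_positions_rejected(self):
        a = self.profile(np.ones(8), length=6.0)
        b = self.profile(np.ones(8), length=5.0)
        with pytest.raises(InvalidParameterError):
            profile_overlap_percent(a, b)

    def test_baseline_subtraction_clips_at_zero(self):
        prof = IntensityProfile.from_raw(np.linspace(0, 6, 5), [10.0, 12.0, 30.0, 12.0, 10.0])
        assert prof.baseline == 10.0
        assert prof.values.min() == 0.0
        assert prof.roi_length == pytest.approx(6.0)
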