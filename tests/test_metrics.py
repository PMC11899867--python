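"""Vascular indices: VD, VLD, VDI and box-counting fractal dimension."""

import math

import numpy as np
import pytest

from asvasc.layers import ROIMask
from asvasc.metrics import (
    box_count,
    compute_metrics,
    default_box_sizes,
    fractal_dimension,
    skeletonize,
    vessel_density,
    vessel_diameter_index,
    vessel_length_density,
)
from asvasc.segmentation import VesselMask
from asvasc.synthetic_data import bar_mask, line_mask, sierpinski_carpet


class TestSkeleton:
    def test_bar_centerline_length(self):
        sk = skeletonize(VesselMask(bar_mask(length=100, width=5)))
        assert 95 <= sk.length_px <= 101

    def test_empty_mask_zero_length(self):
        sk = skeletonize(VesselMask(np.zeros((20, 20), dtype=bool)))
        assert sk.length_px == 0
        assert not sk.pixels.any()

    def test_isolated_pixel_survives_with_zero_length(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 10] = True
        sk = skeletonize(VesselMask(m))
        assert sk.pixels.sum() == 1
        assert sk.length_px == 0

    def test_diagonal_line_length_uses_sqrt2(self):
        m = np.eye(50, dtype=bool)
        sk = skeletonize(VesselMask(m))
        assert sk.length_px == pytest.approx(49 * math.sqrt(2))

    def test_skeleton_subset_of_mask(self, rng):
        m = rng.random((60, 60)) < 0.4
        sk = skeletonize(VesselMask(m))
        assert not (sk.pixels & ~m).any()


class TestAreaLengthIndices:
    def test_vd_mask_equals_roi(self, full_roi):
        mask = VesselMask(full_roi.pixels.copy())
        assert vessel_density(mask, full_roi) == 1.0

    def test_vd_half(self):
        roi = ROIMask(np.ones((10, 10), dtype=bool))
        m = np.zeros((10, 10), dtype=bool)
        m[:5] = True
        assert vessel_density(VesselMask(m), roi) == 0.5

    def test_vd_matches_pixel_count_oracle(self, rng):
        roi_px = rng.random((50, 50)) < 0.8
        roi = ROIMask(roi_px)
        m = roi_px & (rng.random((50, 50)) < 0.3)
        expected = m.sum() / roi_px.sum()
        assert vessel_density(VesselMask(m), roi) == pytest.approx(expected)

    def test_vld_straight_line_closed_form(self, full_roi):
        # 100-px 4-connected line: 99 unit steps over the 304x304 frame
        sk = skeletonize(VesselMask(line_mask(length=100)))
        assert vessel_length_density(sk, full_roi) == pytest.approx(99 / 92416)

    def test_vld_halves_when_roi_doubles(self):
        m = line_mask(length=50, frame=(100, 100))
        sk = skeletonize(VesselMask(m))
        roi_small = ROIMask(np.ones((100, 100), dtype=bool))
        big = np.zeros((200, 100), dtype=bool)
        big[:] = True
        sk_big = skeletonize(VesselMask(np.vstack([m, np.zeros_like(m)])))
        assert vessel_length_density(sk_big, ROIMask(big)) == pytest.approx(
            vessel_length_density(sk, roi_small) / 2
        )

    def test_vdi_bar_approximates_width(self):
        mask = VesselMask(bar_mask(length=100, width=5))
        sk = skeletonize(mask)
        assert vessel_diameter_index(mask, sk) == pytest.approx(5.0, rel=0.10)

    def test_vdi_thin_line_near_one(self):
        mask = VesselMask(line_mask(length=100))
        sk = skeletonize(mask)
        assert vessel_diameter_index(mask, sk) == pytest.approx(100 / 99, rel=0.01)

    def test_vdi_undefined_warns_nan(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 5] = True  # single pixel: mask area 1, skeleton length 0
        mask = VesselMask(m)
        sk = skeletonize(mask)
        with pytest.warns(RuntimeWarning):
            assert math.isnan(vessel_diameter_index(mask, sk))

    def test_identity_vdi_vld_vd_on_random_masks(self, rng, full_roi):
        """The algebraic identity VDI * VLD == VD on 100 seeded masks."""
        for _ in range(100):
            m = rng.random((304, 304)) < rng.uniform(0.05, 0.6)
            mask = VesselMask(m)
            sk = skeletonize(mask)
            if sk.length_px == 0:
                continue
            vd = vessel_density(mask, full_roi)
            vld = vessel_length_density(sk, full_roi)
            vdi = vessel_diameter_index(mask, sk)
            assert abs(vdi * vld - vd) < 1e-12

    def test_dilation_never_decreases_vd(self, rng, full_roi):
        from scipy import ndimage

        m = rng.random((304, 304)) < 0.2
        vd0 = vessel_density(VesselMask(m), full_roi)
        vd1 = vessel_density(
            VesselMask(ndimage.binary_dilation(m)), full_roi
        )
        assert vd1 >= vd0


class TestBoxCount:
    def test_full_square_closed_form(self):
        roi = ROIMask(np.ones((256, 256), dtype=bool))
        mask = VesselMask(np.ones((256, 256), dtype=bool))
        sizes = [1, 2, 4, 8, 16, 32, 64, 128]
        series = box_count(mask, roi, sizes)
        np.testing.assert_array_equal(series.counts, [(256 // e) ** 2 for e in sizes])

    def test_single_pixel_always_one_box(self):
        m = np.zeros((64, 64), dtype=bool)
        m[10, 20] = True
        roi = ROIMask(np.ones((64, 64), dtype=bool))
        series = box_count(VesselMask(m), roi, [1, 2, 4, 8])
        np.testing.assert_array_equal(series.counts, [1, 1, 1, 1])

    def test_matches_brute_force_grid_scan(self, rng):
        roi = ROIMask(np.ones((73, 89), dtype=bool))  # non-dyadic extents
        for _ in range(5):
            m = rng.random((73, 89)) < 0.1
            if not m.any():
                continue
            series = box_count(VesselMask(m), roi, [2, 3, 5, 8])
            for e, n in zip(series.sizes, series.counts):
                count = 0
                for r0 in range(0, 73, e):
                    for c0 in range(0, 89, e):
                        if m[r0 : r0 + e, c0 : c0 + e].any():
                            count += 1
                assert n == count

    def test_counts_non_increasing_and_cover_pixels(self, rng):
        roi = ROIMask(np.ones((100, 100), dtype=bool))
        m = rng.random((100, 100)) < 0.3
        series = box_count(VesselMask(m), roi, [2, 4, 8, 16])
        assert np.all(np.diff(series.counts) <= 0)
        assert np.all(series.counts * series.sizes**2 >= m.sum())

    def test_empty_mask_errors(self):
        roi = ROIMask(np.ones((10, 10), dtype=bool))
        with pytest.raises(ValueError, match="undefined on empty"):
            box_count(VesselMask(np.zeros((10, 10), dtype=bool)), roi, [1, 2])


class TestFractalDimension:
    def test_filled_square_dimension_two(self):
        roi = ROIMask(np.ones((256, 256), dtype=bool))
        mask = VesselMask(np.ones((256, 256), dtype=bool))
        fd = fractal_dimension(box_count(mask, roi, [2, 4, 8, 16, 32, 64]))
        assert fd == pytest.approx(2.0, abs=0.05)

    def test_line_dimension_one(self, full_roi):
        fd = fractal_dimension(box_count(VesselMask(line_mask()), full_roi,
                                         [2, 4, 8, 16, 32, 64]))
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet_dimension(self):
        carpet = sierpinski_carpet(5)  # 243 x 243
        roi = ROIMask(np.ones(carpet.shape, dtype=bool))
        fd = fractal_dimension(box_count(VesselMask(carpet), roi, [1, 3, 9, 27, 81]))
        assert fd == pytest.approx(math.log(8) / math.log(3), abs=0.05)

    def test_requires_three_sizes(self):
        roi = ROIMask(np.ones((32, 32), dtype=bool))
        series = box_count(VesselMask(np.ones((32, 32), dtype=bool)), roi, [2, 4])
        with pytest.raises(ValueError, match=">= 3"):
            fractal_dimension(series)

    def test_fd_within_plane_bounds(self, rng, full_roi):
        for _ in range(10):
            m = rng.random((304, 304)) < rng.uniform(0.02, 0.7)
            fd = fractal_dimension(box_count(VesselMask(m), full_roi))
            assert -0.1 <= fd <= 2.1


class TestComputeMetrics:
    def test_composition_matches_individual_ops(self, full_roi):
        mask = VesselMask(bar_mask())
        m = compute_metrics(mask, full_roi)
        sk = skeletonize(mask)
        assert m.vd == vessel_density(mask, full_roi)
        assert m.vld == vessel_length_density(sk, full_roi)
        assert m.vdi == vessel_diameter_index(mask, sk)
        assert m.fd == fractal_dimension(box_count(mask, full_roi))

    def test_empty_mask_flagged_undefined(self, full_roi):
        m = compute_metrics(VesselMask(np.zeros((304, 304), dtype=bool)), full_roi)
        assert m.vd == 0.0 and m.vld == 0.0
        assert math.isnan(m.vdi) and math.isnan(m.fd)

    def test_translation_invariance(self, full_roi):
        m1 = bar_mask(frame=(304, 304))
        m2 = np.roll(m1, (31, 17), axis=(0, 1))
        a = compute_metrics(VesselMask(m1), full_roi)
        b = compute_metrics(VesselMask(m2), full_roi)
        assert a.vd == b.vd
        assert a.vld == b.vld
        assert a.vdi == b.vdi
        assert abs(a.fd - b.fd) < 0.05  # grid anchoring shifts boxes slightly

    def test_default_box_sizes_dyadic(self, full_roi):
        assert default_box_sizes(full_roi) == [2, 4, 8, 16, 32, 64]
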