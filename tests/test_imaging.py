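"""Imaging stage: focal fusion, thresholding and the row/column peak finder."""

import numpy as np
import pytest

from mldcyto import (FrameStack, apply_threshold, compute_threshold,
                     detect_peaks, fuse_focal_planes)
from mldcyto.imaging import _gradient_energy

from conftest import gaussian_spot, make_composite


def brute_force_fusion(planes, region_px):
    """Independent block-by-block gradient-sum evaluation."""
    n, h, w = planes.shape
    out = np.empty((h, w))
    src = np.empty((h, w), dtype=int)
    for y0 in range(0, h, region_px):
        for x0 in range(0, w, region_px):
            y1, x1 = min(y0 + region_px, h), min(x0 + region_px, w)
            best, best_sum = 0, -1.0
            for p in range(n):
                blk = planes[p].astype(float)
                s = 0.0
                for y in range(y0, y1):
                    for x in range(x0, x1 - 1):
                        s += abs(blk[y, x + 1] - blk[y, x])
                for y in range(y0, y1 - 1):
                    for x in range(x0, x1):
                        s += abs(blk[y + 1, x] - blk[y, x])
                if s > best_sum:
                    best, best_sum = p, s
            out[y0:y1, x0:x1] = planes[best, y0:y1, x0:x1]
            src[y0:y1, x0:x1] = best
    return out, src


class TestFusion:
    def test_single_plane_identity(self, rng):
        img = rng.integers(0, 100, (20, 20))
        stack = FrameStack(img[None], 0, 0.0)
        comp = fuse_focal_planes(stack, 8)
        assert np.array_equal(comp.intensity, img)
        assert np.all(comp.source_plane == 0)

    def test_sharp_block_wins_and_ties_break_low(self):
        h = w = 16
        plane0 = np.full((h, w), 10.0)
        plane1 = np.full((h, w), 10.0)
        plane1[4, 4] = 200.0  # sharp spot in the first 8x8 block
        stack = FrameStack(np.stack([plane0, plane1]), 0, 0.0)
        comp = fuse_focal_planes(stack, 8)
        assert np.all(comp.source_plane[:8, :8] == 1)
        # uniform-vs-uniform blocks tie-break to plane 0
        assert np.all(comp.source_plane[8:, 8:] == 0)
        assert comp.intensity[4, 4] == 200.0

    def test_identical_planes_give_that_plane(self, rng):
        img = rng.normal(50, 5, (24, 24))
        stack = FrameStack(np.stack([img, img]), 0, 0.0)
        comp = fuse_focal_planes(stack, 8)
        assert np.allclose(comp.intensity, img)

    @pytest.mark.parametrize("shape,region", [((17, 23), 8), ((64, 64), 32),
                                              ((33, 15), 5)])
    def test_matches_brute_force_oracle(self, rng, shape, region):
        planes = rng.integers(0, 255, (3, *shape)).astype(float)
        stack = FrameStack(planes, 0, 0.0)
        comp = fuse_focal_planes(stack, region)
        expect, expect_src = brute_force_fusion(planes, region)
        assert np.array_equal(comp.intensity, expect)
        assert np.array_equal(comp.source_plane, expect_src)

    def test_oversize_region_falls_back_to_whole_image(self, rng):
        planes = rng.normal(0, 1, (2, 10, 10))
        comp = fuse_focal_planes(FrameStack(planes, 0, 0.0), 100)
        assert len(np.unique(comp.source_plane)) == 1

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            FrameStack(np.zeros((0, 4, 4)), 0, 0.0)

    def test_gradient_energy_counts_each_difference_once(self):
        img = np.array([[0.0, 3.0], [1.0, 1.0]])
        # |3-0| + |1-1| horizontal, |1-0| + |1-3| vertical = 3 + 0 + 1 + 2
        assert _gradient_energy(img).sum() == 6.0


class TestThreshold:
    def test_constant_image(self):
        assert compute_threshold(make_composite(np.full((5, 5), 7.0))) == 7.0

    def test_hand_computed_example(self):
        img = make_composite(np.array([[0.0, 0.0], [0.0, 4.0]]))
        # mu = 1, population sigma = sqrt(3)
        assert compute_threshold(img) == pytest.approx(1 + np.sqrt(3))

    def test_gaussian_noise_monte_carlo(self, rng):
        img = make_composite(rng.normal(400, 100, (1000, 1000)))
        assert compute_threshold(img) == pytest.approx(500, abs=1.5)

    def test_sample_sigma_option(self):
        img = make_composite(np.array([[0.0, 0.0], [0.0, 4.0]]))
        expect = 1 + np.std([0, 0, 0, 4], ddof=1)
        assert compute_threshold(img, population=False) == pytest.approx(expect)

    def test_step_function_bounds(self, rng):
        img = make_composite(rng.uniform(1, 10, (12, 12)))
        assert not apply_threshold(img, img.intensity.max() + 1).any()
        assert apply_threshold(img, -1.0).all()  # clamped to 0, all positive

    def test_mask_count_non_increasing_in_theta(self, rng):
        img = make_composite(rng.normal(100, 30, (40, 40)))
        counts = [apply_threshold(img, th).sum()
                  for th in np.linspace(0, 200, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def exhaustive_local_maxima(data, mask, window):
    """Oracle: pixels that are >= every pixel of their full square window."""
    h, w = data.shape
    r = window // 2
    hits = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            block = data[max(0, y - r):y + r + 1, max(0, x - r):x + r + 1]
            if data[y, x] >= block.max():
                hits.append((x, y))
    return hits


class TestPeakFinder:
    def test_single_gaussian_spot(self):
        img = make_composite(gaussian_spot((31, 31), 14, 17, 1000.0))
        mask = img.intensity > 100
        emap = detect_peaks(img, mask, 5)
        assert len(emap) == 1
        assert tuple(emap.elements[0]) == (14, 17)

    def test_two_separated_spots_match_exhaustive_search(self):
        img = gaussian_spot((41, 41), 8, 9, 900.0) + \
            gaussian_spot((41, 41), 30, 28, 700.0)
        comp = make_composite(img)
        mask = comp.intensity > 80
        emap = detect_peaks(comp, mask, 5)
        assert len(emap) == 2
        oracle = exhaustive_local_maxima(comp.intensity, mask, 5)
        for x, y in emap.elements:
            assert any(abs(x - ox) <= 1 and abs(y - oy) <= 1
                       for ox, oy in oracle)

    def test_empty_mask(self, rng):
        comp = make_composite(rng.normal(0, 1, (10, 10)))
        emap = detect_peaks(comp, np.zeros((10, 10), dtype=bool), 5)
        assert len(emap) == 0

    def test_plateau_yields_single_element_lowest_y_then_x(self):
        img = np.zeros((11, 11))
        img[5, 4:7] = 9.0  # 3-pixel plateau
        comp = make_composite(img)
        emap = detect_peaks(comp, img > 1, 5)
        assert len(emap) == 1
        assert tuple(emap.elements[0]) == (4, 5)

    def test_element_count_monotone_in_threshold(self, rng):
        img = rng.normal(100, 30, (64, 64))
        for cx, cy in [(10, 12), (40, 30), (55, 50)]:
            img += gaussian_spot((64, 64), cx, cy, 500.0)
        comp = make_composite(img)
        counts = []
        for th in np.linspace(50, 600, 12):
            counts.append(len(detect_peaks(comp, comp.intensity > th, 5)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_window_validation(self):
        comp = make_composite(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            detect_peaks(comp, np.ones((5, 5), dtype=bool), 4)

    def test_well_separated_spots_agree_with_skimage(self, rng):
        """Independent library oracle on a field of isolated spots."""
        from skimage.feature import peak_local_max

        img = np.zeros((120, 120))
        centres = [(15, 20), (60, 30), (100, 95), (25, 100), (80, 70)]
        for cy, cx in centres:
            img += gaussian_spot((120, 120), cx, cy, 1000 * (1 + rng.uniform()))
        comp = make_composite(img)
        mask = comp.intensity > 150
        emap = detect_peaks(comp, mask, 5)
        ref = peak_local_max(comp.intensity, min_distance=2,
                             threshold_abs=150)
        assert len(emap) == len(centres) == len(ref)
        ref_xy = {(int(x), int(y)) for y, x in ref}
        got_xy = {(int(x), int(y)) for x, y in emap.elements}
        assert got_xy == ref_xy
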