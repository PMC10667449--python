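"""TI-selection pipeline: ROI geometry, histograms, threshold, selection.

Each operation is checked against an independent brute-force oracle that
re-derives the quantity by direct per-pixel enumeration.
"""

import numpy as np
import pytest

from tiscout import (
    DEFAULT_ROI_SPEC,
    DegenerateRoiError,
    RoiSpec,
    ShimBox,
    compute_histograms,
    count_subthreshold,
    derive_roi,
    find_threshold,
    select_ti,
)
from tiscout.phantom import PhantomSpec, TissueParams, generate_scout, ground_truth_ti

from conftest import make_series, random_series


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_selection(series, roi_mask, mode="inclusive"):
    """Re-derive (s_thr, alpha, g, selected index) by explicit loops."""
    max_pi = series.max_pi
    hists = []
    for image in series.images:
        h = [0] * (max_pi + 1)
        rows, cols = image.pixels.shape
        for r in range(rows):
            for c in range(cols):
                if roi_mask[r, c]:
                    h[int(image.pixels[r, c])] += 1
        hists.append(h)
    # per-image peak: tallest bin, lowest level on ties
    peaks = []
    for n, h in enumerate(hists):
        count, level = max((cnt, -i) for i, cnt in enumerate(h))
        peaks.append((count, level, n))  # level stored negated: max -> min level
    # global peak: tallest, then lowest modal level, then lowest image index
    _, neg_level, alpha = max(peaks, key=lambda t: (t[0], t[1], -t[2]))
    s_thr = -neg_level
    top = s_thr + 1 if mode == "inclusive" else s_thr
    g = [sum(h[:top]) for h in hists]
    selected = max(range(len(g)), key=lambda n: (g[n], -n))
    return s_thr, alpha, g, selected


def brute_force_disk_count(shim, divisor, grid_shape):
    radius = min(shim.width, shim.height) / divisor / 2.0
    cx, cy = shim.x0 + shim.width / 2.0, shim.y0 + shim.height / 2.0
    count = 0
    for r in range(grid_shape[0]):
        for c in range(grid_shape[1]):
            if (c + 0.5 - cx) ** 2 + (r + 0.5 - cy) ** 2 <= radius**2:
                count += 1
    return count


# ---------------------------------------------------------------------------
# ROI derivation
# ---------------------------------------------------------------------------

class TestDeriveRoi:
    def test_divisor_one_is_shim_interior(self):
        shim = ShimBox(20, 30, 100, 80)
        roi = derive_roi(shim, RoiSpec("rectangle", 1.0), (160, 160))
        assert roi.pixel_count == 8000
        expected = np.zeros((160, 160), dtype=bool)
        expected[30:110, 20:120] = True
        assert np.array_equal(roi.mask, expected)

    def test_rectangle_concentric_shrink(self):
        shim = ShimBox(20, 30, 100, 80)
        roi = derive_roi(shim, RoiSpec("rectangle", 2.5), (160, 160))
        assert roi.pixel_count == 40 * 32
        rows = np.flatnonzero(roi.mask.any(axis=1))
        cols = np.flatnonzero(roi.mask.any(axis=0))
        # concentric with the shim box
        assert rows[0] - 30 == 110 - 1 - rows[-1]
        assert cols[0] - 20 == 120 - 1 - cols[-1]

    @pytest.mark.parametrize("divisor", [1.0, 1.7, 2.2, 3.3, 4.0])
    def test_circle_matches_brute_force(self, divisor):
        shim = ShimBox(10, 15, 100, 80)
        roi = derive_roi(shim, RoiSpec("circle", divisor), (120, 130))
        assert roi.pixel_count == brute_force_disk_count(shim, divisor, (120, 130))
        # every ROI pixel lies inside the shim box
        outside = roi.mask.copy()
        outside[15:95, 10:110] = False
        assert not outside.any()

    def test_degenerate_roi_raises(self):
        # a rectangle never shrinks below its 4x4 floor, but a disk can
        shim = ShimBox(2, 2, 8, 8)
        with pytest.raises(DegenerateRoiError):
            derive_roi(shim, RoiSpec("circle", 4.0), (16, 16))

    def test_rectangle_area_law(self):
        # pixel_count ~ shim area / k^2 within 10% for k <= 4
        shim = ShimBox(5, 5, 100, 80)
        for k in np.arange(1.0, 4.05, 0.1):
            roi = derive_roi(shim, RoiSpec("rectangle", float(k)), (128, 128))
            expected = 8000 / k**2
            assert abs(roi.pixel_count - expected) / expected < 0.10


# ---------------------------------------------------------------------------
# histograms / threshold / counting
# ---------------------------------------------------------------------------

class TestHistograms:
    def test_direct_count(self):
        from tiscout import RoiMask

        img = np.full((4, 4), 9)
        img[0, 0] = img[0, 1] = 0
        img[1, 0] = 1
        img[1, 1] = 255
        series = make_series([img, img], [60, 70], shim=ShimBox(0, 0, 4, 4), max_pi=255)
        roi = RoiMask(np.ones(img.shape, dtype=bool))
        h = compute_histograms(series, roi)
        assert h[0][0] == 2 and h[0][1] == 1 and h[0][255] == 1 and h[0][9] == 12
        assert h[0].sum() == roi.pixel_count

    def test_uniform_image_degenerate_histogram(self):
        img = np.full((6, 6), 7)
        series = make_series([img, img], [60, 70], max_pi=255)
        roi = derive_roi(series.shim, RoiSpec("rectangle", 1.0), series.grid_shape)
        h = compute_histograms(series, roi)
        assert h[0][7] == roi.pixel_count
        assert h[0].sum() == roi.pixel_count

    def test_random_matches_brute_force(self, rng):
        series = random_series(rng, n_images=2, shape=(20, 20), max_pi=63)
        roi = derive_roi(series.shim, RoiSpec("rectangle", 1.3), series.grid_shape)
        h = compute_histograms(series, roi)
        for n, image in enumerate(series.images):
            tally = np.zeros(64, dtype=int)
            for r in range(20):
                for c in range(20):
                    if roi.mask[r, c]:
                        tally[image.pixels[r, c]] += 1
            assert np.array_equal(h[n], tally)


class TestFindThreshold:
    def _hists(self, peaks, nbins=16):
        """Histogram set with prescribed (count, level) peaks per image."""
        h = np.ones((len(peaks), nbins), dtype=int)
        for n, (count, level) in enumerate(peaks):
            h[n, level] = count
        return h

    def test_global_peak_selects_alpha_and_threshold(self):
        h = self._hists([(5, 3), (9, 2), (7, 10)])
        s_thr, alpha = find_threshold(h)
        assert (s_thr, alpha) == (2, 1)

    def test_image_tie_breaks_to_lower_ti(self):
        # equal peak heights at equal modal levels: lower TI wins
        h = self._hists([(9, 2), (9, 2)])
        s_thr, alpha = find_threshold(h)
        assert alpha == 0 and s_thr == 2

    def test_image_tie_prefers_lower_modal_level(self):
        # equal peak heights: the better-nulled image (lower mode) sets S_thr
        h = self._hists([(9, 4), (9, 2)])
        s_thr, alpha = find_threshold(h)
        assert alpha == 1 and s_thr == 2

    def test_level_tie_breaks_to_lower_level(self):
        h = np.ones((1, 16), dtype=int)
        h[0, 5] = h[0, 9] = 7
        s_thr, alpha = find_threshold(h)
        assert s_thr == 5

    def test_random_matches_exhaustive_scan(self, rng):
        for _ in range(5):
            h = rng.integers(0, 30, size=(4, 24))
            s_thr, alpha = find_threshold(h)
            per_image = []
            for n in range(4):
                peak = max(h[n])
                mode = min(i for i in range(24) if h[n, i] == peak)
                per_image.append((-peak, mode, n))
            exp_alpha = min(per_image)[2]
            assert (alpha, s_thr) == (exp_alpha, min(per_image)[1])


class TestCountSubthreshold:
    @pytest.mark.parametrize("mode,expected", [("inclusive", 3), ("strict", 2)])
    def test_conventions(self, mode, expected):
        h = np.zeros((1, 8), dtype=int)
        h[0, :5] = 1  # ROI pixels 0..4
        assert count_subthreshold(h, 2, mode)[0] == expected

    def test_saturation_at_max_pi(self):
        h = np.array([[3, 1, 4, 1, 5]])
        assert count_subthreshold(h, 4, "inclusive")[0] == h.sum()


# ---------------------------------------------------------------------------
# end-to-end selection
# ---------------------------------------------------------------------------

class TestSelectTi:
    def test_constructed_low_intensity_majority(self, rng):
        shape = (20, 20)
        shim = ShimBox(2, 2, 16, 16)
        spec = RoiSpec("rectangle", 1.0)
        # interior pixel grid: image with most near-zero ROI pixels must win
        base = [rng.integers(100, 200, size=shape) for _ in range(3)]
        roi = derive_roi(shim, spec, shape)
        coords = np.argwhere(roi.mask)
        for arr, n_low in zip(base, (10, 30, 12)):
            for r, c in coords[:n_low]:
                arr[r, c] = 0
        series = make_series(base, [60, 90, 120], shim=shim, max_pi=255)
        result = select_ti(series, spec)
        assert result.selected_ti_ms == 90.0
        s_thr, alpha, g, sel = brute_force_selection(series, roi.mask)
        assert result.threshold == s_thr
        assert result.selected_index == sel

    def test_all_zero_image_wins(self):
        shape = (16, 16)
        max_pi = 255
        arrays = [np.full(shape, max_pi), np.zeros(shape, dtype=int), np.full(shape, max_pi)]
        series = make_series(arrays, [60, 70, 80], max_pi=max_pi)
        assert select_ti(series).selected_ti_ms == 70.0

    def test_noiseless_phantom_recovers_truth(self):
        # blood and myocardium nulling together at ~110 ms
        spec = PhantomSpec(
            blood=TissueParams(600.0, 159.4),
            myocardium=TissueParams(400.0, 159.4),
            noise_sigma=0.0,
        )
        assert ground_truth_ti(spec) == 110.0
        result = select_ti(generate_scout(spec))
        assert result.selected_ti_ms == 110.0

    def test_selected_ti_always_on_grid(self, rng):
        for _ in range(5):
            series = random_series(rng, n_images=4)
            assert select_ti(series).selected_ti_ms in series.ti_grid_ms


class TestInvariances:
    def test_shift_invariance(self, rng):
        series = random_series(rng, n_images=3, max_pi=200)
        c = 17
        shifted = make_series(
            [im.pixels + c for im in series.images],
            list(series.ti_grid_ms),
            shim=series.shim,
            max_pi=series.max_pi + c,
        )
        r0, r1 = select_ti(series), select_ti(shifted)
        assert r1.selected_ti_ms == r0.selected_ti_ms
        assert r1.threshold == r0.threshold + c

    def test_integer_scale_invariance(self, rng):
        series = random_series(rng, n_images=3, max_pi=100)
        m = 3
        scaled = make_series(
            [im.pixels * m for im in series.images],
            list(series.ti_grid_ms),
            shim=series.shim,
            max_pi=series.max_pi * m,
        )
        assert select_ti(scaled).selected_ti_ms == select_ti(series).selected_ti_ms

    def test_permutation_invariance(self, rng):
        series = random_series(rng, n_images=4)
        perm = [2, 0, 3, 1]
        shuffled = make_series(
            [series.images[i].pixels for i in perm],
            [series.ti_grid_ms[i] for i in perm],
            shim=series.shim,
            max_pi=series.max_pi,
        )
        assert select_ti(shuffled) == select_ti(series)
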