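import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from endoclear import metrics as mt
from endoclear.masking import HighlightMask, SoftThresholds

THR = SoftThresholds(s_tau=0.3, v_tau=0.7, s_hard=0.3, v_hard=0.7, s_mean=0.5, v_mean=0.5)

TISSUE = (200.0, 100.0, 100.0)  # S = 0.5, V ~ 0.78: never qualifies
WHITE = (255.0, 255.0, 255.0)  # S = 0, V = 1: always qualifies


def _image(shape=(10, 10), fill=TISSUE):
    img = np.empty(shape + (3,))
    img[:] = fill
    return img


class TestHighlightPercentage:
    def test_counts_qualifying_pixels(self):
        img = _image()
        img[0, :5] = WHITE
        assert mt.highlight_percentage(img, THR) == pytest.approx(5.0)

    def test_extremes(self):
        assert mt.highlight_percentage(_image(), THR) == 0.0
        assert mt.highlight_percentage(_image(fill=WHITE), THR) == 100.0

    def test_monotone_in_qualifying_count(self):
        values = []
        for k in (0, 3, 7, 10):
            img = _image()
            img[2, :k] = WHITE
            values.append(mt.highlight_percentage(img, THR))
        assert values == sorted(values)


def _flood_fill_components(mask):
    """Brute-force 8-connected labeling oracle."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(comp)
    return comps


class TestRegionBoxes:
    def test_single_blob_with_margin(self):
        vals = np.zeros((32, 32), dtype=np.uint8)
        vals[10:13, 10:13] = 1
        (box,) = mt.extract_region_boxes(HighlightMask(vals), margin=2)
        assert (box.top, box.left, box.bottom, box.right) == (8, 8, 15, 15)

    def test_corner_blob_is_clipped(self):
        vals = np.zeros((32, 32), dtype=np.uint8)
        vals[0:2, 0:2] = 1
        (box,) = mt.extract_region_boxes(HighlightMask(vals), margin=5)
        assert (box.top, box.left) == (0, 0)

    def test_empty_mask_yields_no_boxes(self):
        assert mt.extract_region_boxes(HighlightMask(np.zeros((8, 8), dtype=np.uint8))) == []

    def test_component_count_matches_flood_fill(self, rng):
        vals = (rng.random((24, 24)) > 0.85).astype(np.uint8)
        boxes = mt.extract_region_boxes(HighlightMask(vals), margin=0)
        assert len(boxes) == len(_flood_fill_components(vals))

    def test_separated_blobs_give_two_boxes(self):
        vals = np.zeros((16, 16), dtype=np.uint8)
        vals[2, 2] = 1
        vals[6, 6] = 1  # > 1 px apart both diagonally and orthogonally
        assert len(mt.extract_region_boxes(HighlightMask(vals), margin=0)) == 2


def _gray(v):
    """Gray RGB pixel whose HSV value channel equals v."""
    return (v * 255.0, v * 255.0, v * 255.0)


class TestCov:
    def test_constant_region_is_zero(self):
        img = _image(fill=_gray(0.5))
        vals = np.zeros((10, 10), dtype=np.uint8)
        vals[4:6, 4:6] = 1
        cov, per = mt.cov_score(img, HighlightMask(vals), margin=0)
        assert cov == 0.0
        assert per == [(1, 0.0)]

    def test_two_point_population_sigma(self):
        img = _image(fill=_gray(0.25))
        img[5, 5] = _gray(0.75)
        vals = np.zeros((10, 10), dtype=np.uint8)
        vals[5, 4:6] = 1  # box covers exactly the pixels {0.25, 0.75}
        cov, _ = mt.cov_score(img, HighlightMask(vals), margin=0)
        assert cov == pytest.approx(0.5, abs=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        img = np.repeat(rng.uniform(10, 240, size=(12, 12, 1)), 3, axis=2)
        vals = np.zeros((12, 12), dtype=np.uint8)
        vals[3:6, 4:8] = 1
        cov, _ = mt.cov_score(img, HighlightMask(vals), margin=2)
        patch = img[1:8, 2:10, 0] / 255.0
        mean = patch.sum() / patch.size
        sigma = np.sqrt(((patch - mean) ** 2).sum() / patch.size)
        assert cov == pytest.approx(sigma / mean, abs=1e-12)

    def test_scale_invariance(self, rng):
        img = np.repeat(rng.uniform(50, 200, size=(12, 12, 1)), 3, axis=2)
        vals = np.zeros((12, 12), dtype=np.uint8)
        vals[4:7, 4:7] = 1
        mask = HighlightMask(vals)
        cov1, _ = mt.cov_score(img, mask, margin=3)
        cov2, _ = mt.cov_score(img * 0.5, mask, margin=3)
        assert cov1 == pytest.approx(cov2, rel=1e-9)
        assert cov1 >= 0.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no highlight regions"):
            mt.cov_score(_image(), HighlightMask(np.zeros((10, 10), dtype=np.uint8)))


def _reference_ssim(x, y, data_range=1.0):
    """Formula-level SSIM oracle: Gaussian local stats, border cropped."""
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    blur = lambda a: gaussian_filter(a, 1.5, truncate=3.5, mode="nearest")
    ux, uy = blur(x), blur(y)
    vx, vy = blur(x * x) - ux**2, blur(y * y) - uy**2
    cxy = blur(x * y) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    return s[5:-5, 5:-5].mean()


class TestMaskSsim:
    def test_identical_signals_score_one(self, rng):
        vals = (rng.random((32, 32)) > 0.8).astype(np.uint8)
        highlight = np.repeat(vals[:, :, None] * 255.0, 3, axis=2)
        assert mt.mask_ssim(HighlightMask(vals), highlight) == pytest.approx(1.0)

    def test_zero_highlight_scores_below_one(self, rng):
        vals = (rng.random((32, 32)) > 0.8).astype(np.uint8)
        assert mt.mask_ssim(HighlightMask(vals), np.zeros((32, 32, 3))) < 1.0

    def test_matches_independent_implementation(self, rng):
        vals = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        noisy = vals + rng.normal(0, 0.01, size=(32, 32))
        highlight = np.repeat(noisy[:, :, None] * 255.0, 3, axis=2)
        ours = mt.mask_ssim(HighlightMask(vals), highlight)
        ref = _reference_ssim(vals.astype(float), noisy)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_symmetry_via_swapped_gray_inputs(self, rng):
        a = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        b = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        img_a = np.repeat(a[:, :, None] * 255.0, 3, axis=2)
        img_b = np.repeat(b[:, :, None] * 255.0, 3, axis=2)
        s1 = mt.mask_ssim(HighlightMask(a), img_b)
        s2 = mt.mask_ssim(HighlightMask(b), img_a)
        assert s1 == pytest.approx(s2, abs=1e-12)
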