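"""Segmentation chain: red channel, thresholding, geometric filter, skeleton."""

import numpy as np
import pytest
from skimage.draw import disk
from skimage.measure import label as sk_label

import cbmorph as cb
from cbmorph.errors import DegenerateImageError, InvalidInputError
from cbmorph.preprocess import _otsu_threshold
from conftest import random_blobs


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive search over all 255 cut points maximizing between-class variance."""
    counts = np.bincount(gray.ravel(), minlength=256).astype(float)
    i = np.arange(256, dtype=float)
    total = counts.sum()
    best_t, best_v = 0, -1.0
    for t in range(255):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (i[: t + 1] * counts[: t + 1]).sum() / w0
        m1 = (i[t + 1 :] * counts[t + 1 :]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def flood_fill_filter(pattern, config):
    """Independent geometric filter: naive 1-pixel flood fill, same predicates."""
    from cbmorph.preprocess import _circularity
    from skimage.measure import perimeter_crofton

    h, w = pattern.shape
    seen = np.zeros_like(pattern, dtype=bool)
    out = np.zeros_like(pattern, dtype=bool)
    if config.connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    max_area = np.inf if config.max_area is None else config.max_area
    for r0 in range(h):
        for c0 in range(w):
            if not pattern[r0, c0] or seen[r0, c0]:
                continue
            stack, comp = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and pattern[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comp_mask = np.zeros_like(pattern, dtype=bool)
            rows, cols = zip(*comp)
            comp_mask[list(rows), list(cols)] = True
            area = len(comp)
            circ = _circularity(area, perimeter_crofton(comp_mask))
            if (config.min_area <= area <= max_area
                    and config.min_circularity <= circ <= config.max_circularity):
                out |= comp_mask
    return out


class TestRedChannel:
    def test_channel_selection(self):
        img = np.array(
            [[[10, 20, 30], [40, 50, 60]], [[70, 80, 90], [0, 0, 0]]], dtype=np.uint8
        )
        assert np.array_equal(cb.extract_red_channel(img), [[10, 40], [70, 0]])

    def test_rejects_wrong_shape_and_depth(self):
        with pytest.raises(InvalidInputError):
            cb.extract_red_channel(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            cb.extract_red_channel(np.zeros((4, 4, 3), dtype=np.uint16))


class TestThreshold:
    def test_bimodal_otsu_dark_foreground(self):
        g = np.array([10] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
        fg = cb.threshold(g, cb.SegmentationConfig())
        assert np.array_equal(fg, g == 10)

    def test_otsu_matches_exhaustive_search(self, rng):
        for _ in range(50):
            g = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
            assert _otsu_threshold(g) == brute_force_otsu(g)

    def test_constant_image_degenerate(self):
        g = np.full((8, 8), 7, dtype=np.uint8)
        with pytest.raises(DegenerateImageError):
            cb.threshold(g, cb.SegmentationConfig())

    def test_manual_mode_no_degeneracy(self):
        g = np.full((8, 8), 200, dtype=np.uint8)
        cfg = cb.SegmentationConfig(
            threshold_method="manual", manual_threshold=128, polarity="bright_foreground"
        )
        assert cb.threshold(g, cfg).all()


class TestGeometricFilter:
    def test_small_component_removed(self):
        pat = np.zeros((10, 10), dtype=bool)
        pat[0, :3] = True
        cfg = cb.SegmentationConfig(min_area=5)
        assert not cb.geometric_filter(pat, cfg).any()

    def test_area_band_keeps_large(self):
        pat = np.zeros((20, 20), dtype=bool)
        pat[0, 0:2] = pat[1, 0:2] = True  # area 4
        pat[5:15, 5:15] = True  # area 100
        cfg = cb.SegmentationConfig(min_area=10)
        out = cb.geometric_filter(pat, cfg)
        assert out.sum() == 100 and out[5:15, 5:15].all()

    def test_idempotent_and_never_adds(self, rng):
        cfg = cb.SegmentationConfig(min_area=10, min_circularity=0.05)
        for _ in range(10):
            pat = random_blobs(rng)
            out = cb.geometric_filter(pat, cfg)
            assert not (out & ~pat).any()
            assert np.array_equal(cb.geometric_filter(out, cfg), out)

    def test_matches_flood_fill_oracle(self, rng):
        cfg = cb.SegmentationConfig(min_area=8, min_circularity=0.1, connectivity=8)
        for _ in range(20):
            pat = random_blobs(rng, shape=(32, 32), sigma=1.5, thresh=0.3)
            assert np.array_equal(cb.geometric_filter(pat, cfg), flood_fill_filter(pat, cfg))


class TestAreaFraction:
    def test_fraction_values(self):
        pat = np.zeros((10, 10), dtype=bool)
        pat.flat[:40] = True
        assert cb.area_fraction(pat) == 0.40
        assert cb.area_fraction(np.zeros((5, 5), dtype=bool)) == 0.0

    def test_zero_size_rejected(self):
        with pytest.raises(InvalidInputError):
            cb.area_fraction(np.zeros((0, 5), dtype=bool))


class TestSkeletonize:
    def test_thin_line_unchanged(self):
        pat = np.zeros((5, 20), dtype=bool)
        pat[2, 2:18] = True
        assert np.array_equal(cb.skeletonize(pat), pat)

    def test_empty_unchanged(self):
        pat = np.zeros((5, 5), dtype=bool)
        assert not cb.skeletonize(pat).any()

    def test_disk_collapses_to_connected_core(self):
        pat = np.zeros((20, 20), dtype=bool)
        rr, cc = disk((10, 10), 8)
        pat[rr, cc] = True
        sk = cb.skeletonize(pat)
        assert 1 <= sk.sum() <= 5
        assert sk_label(sk, connectivity=2).max() <= 1

    def test_subset_idempotent_components_preserved(self, rng):
        for _ in range(10):
            pat = random_blobs(rng)
            sk = cb.skeletonize(pat)
            assert not (sk & ~pat).any()
            assert sk.sum() <= pat.sum()
            assert np.array_equal(cb.skeletonize(sk), sk)
            assert sk_label(sk, connectivity=2).max() == sk_label(pat, connectivity=2).max()


class TestSegmentationRecoversTruth:
    def test_jaccard_against_generator_truth(self):
        """Red channel + Otsu + filter recovers the known connective mask."""
        cfg = cb.SegmentationConfig()
        for seed in (1, 2, 3):
            spec = cb.SyntheticTissueSpec(width=128, height=128, stain_noise_sd=10.0, seed=seed)
            rgb, truth = cb.make_tissue_image(spec)
            mask = cb.geometric_filter(cb.threshold(cb.extract_red_channel(rgb), cfg), cfg)
            jacc = (mask & truth.mask).sum() / (mask | truth.mask).sum()
            assert jacc >= 0.9
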