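"""Box counting, fractal dimension, and lacunarity against analytic values
and naive oracles."""

import math

import numpy as np
import pytest

import cbmorph as cb
from cbmorph.errors import EmptyPatternError, InvalidArgumentError
from cbmorph.fractal import default_sizes


def brute_force_box_count(pattern, size, origin):
    """Per-pixel bucketing into plane-tiling boxes."""
    boxes = set()
    for r in range(pattern.shape[0]):
        for c in range(pattern.shape[1]):
            if pattern[r, c]:
                boxes.add(((r + origin[0]) // size, (c + origin[1]) // size))
    return len(boxes)


def brute_force_box_masses(pattern, size, origin):
    """Materialize every fully-inside box and sum its pixels."""
    h, w = pattern.shape
    masses = []
    start_r = (-origin[0]) % size
    start_c = (-origin[1]) % size
    for a in range(start_r, h - size + 1, size):
        for b in range(start_c, w - size + 1, size):
            masses.append(int(pattern[a : a + size, b : b + size].sum()))
    return np.array(masses)


class TestBoxCounts:
    def test_filled_square_examples(self):
        sq = cb.make_filled_rect(8, 8)
        assert cb.box_counts(sq, 2, (0, 0)) == 16
        line = cb.make_filled_rect(64, 1)
        assert [cb.box_counts(line, s) for s in (1, 2, 4, 8)] == [64, 32, 16, 8]

    def test_matches_bucketing_oracle(self, rng):
        for _ in range(30):
            pat = rng.random((64, 64)) < rng.uniform(0.02, 0.3)
            size = int(rng.integers(1, 17))
            origin = (int(rng.integers(size)), int(rng.integers(size)))
            assert cb.box_counts(pat, size, origin) == brute_force_box_count(pat, size, origin)

    def test_empty_pattern_zero(self):
        assert cb.box_counts(np.zeros((8, 8), dtype=bool), 2) == 0

    def test_origin_validation(self):
        with pytest.raises(InvalidArgumentError):
            cb.box_counts(np.ones((8, 8), dtype=bool), 2, (3, 0))


class TestBoxMasses:
    def test_matches_materialized_oracle(self, rng):
        for _ in range(30):
            pat = rng.random((64, 64)) < rng.uniform(0.05, 0.5)
            size = int(rng.integers(2, 17))
            origin = (int(rng.integers(size)), int(rng.integers(size)))
            np.testing.assert_array_equal(
                cb.box_masses(pat, size, origin), brute_force_box_masses(pat, size, origin)
            )


class TestFractalDimension:
    def test_filled_square_dimension_two(self):
        res = cb.fractal_dimension(
            cb.make_filled_rect(8, 8), cb.BoxGridSpec(sizes=(1, 2, 4, 8), n_origins=1)
        )
        assert res.mean_D == pytest.approx(2.0, abs=1e-9)

    def test_line_dimension_one(self):
        res = cb.fractal_dimension(
            cb.make_filled_rect(64, 1), cb.BoxGridSpec(sizes=(1, 2, 4, 8), n_origins=1)
        )
        assert res.mean_D == pytest.approx(1.0, abs=1e-9)

    def test_sierpinski_counts_and_dimension(self):
        carpet = cb.make_sierpinski_carpet(5)
        counts = [cb.box_counts(carpet, 3**k) for k in range(6)]
        assert counts == [8**5, 8**4, 8**3, 8**2, 8, 1]
        res = cb.fractal_dimension(
            carpet, cb.BoxGridSpec(sizes=(1, 3, 9, 27, 81), n_origins=1)
        )
        assert res.mean_D == pytest.approx(math.log(8) / math.log(3), abs=1e-9)

    def test_mean_is_average_of_origins(self, rng):
        pat = rng.random((64, 64)) < 0.2
        res = cb.fractal_dimension(pat, cb.BoxGridSpec(sizes=(2, 4, 8, 16), n_origins=5, seed=3))
        assert len(res.per_origin_D) == 5
        assert res.mean_D == pytest.approx(np.mean(res.per_origin_D))

    def test_determinism_same_seed(self, rng):
        pat = rng.random((64, 64)) < 0.2
        g = cb.BoxGridSpec(sizes=(2, 4, 8, 16), n_origins=8, seed=11)
        assert cb.fractal_dimension(pat, g).per_origin_D == cb.fractal_dimension(pat, g).per_origin_D

    def test_translation_consistency(self):
        """Multi-origin averaging keeps D stable under pattern translation."""
        carpet = cb.make_sierpinski_carpet(4)  # 81x81
        canvas = np.zeros((96, 96), dtype=bool)
        canvas[:81, :81] = carpet
        shifted = np.zeros((96, 96), dtype=bool)
        shifted[3:84, 5:86] = carpet
        g = cb.BoxGridSpec(sizes=(2, 4, 8, 16), n_origins=10, seed=0)
        d1 = cb.fractal_dimension(canvas, g).mean_D
        d2 = cb.fractal_dimension(shifted, g).mean_D
        assert abs(d1 - d2) < 0.03

    def test_too_few_foreground_rejected(self):
        pat = np.zeros((16, 16), dtype=bool)
        pat[0, 0] = True
        with pytest.raises(EmptyPatternError):
            cb.fractal_dimension(pat, cb.BoxGridSpec(sizes=(2, 4)))

    def test_grid_spec_validation(self):
        with pytest.raises(InvalidArgumentError):
            cb.BoxGridSpec(sizes=(4,))  # need >= 2 sizes for a regression
        with pytest.raises(InvalidArgumentError):
            cb.BoxGridSpec(sizes=(4, 4, 8))  # strictly increasing
        with pytest.raises(InvalidArgumentError):
            cb.BoxGridSpec(sizes=(2, 4), n_origins=0)


class TestLacunarity:
    def test_filled_image_zero(self):
        g = cb.BoxGridSpec(sizes=(2, 4, 8), n_origins=1)
        assert cb.lacunarity(cb.make_filled_rect(32, 32), g) == 0.0

    def test_half_filled_two_boxes(self):
        pat = np.zeros((8, 16), dtype=bool)
        pat[:, :8] = True
        val = cb.lacunarity(pat, cb.BoxGridSpec(sizes=(8, 16), n_origins=1))
        # size 8: two boxes (m, 0) -> cv = 1; size 16: no fully-inside box
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_cv_squared_mode(self):
        pat = np.zeros((8, 16), dtype=bool)
        pat[:, :8] = True
        g = cb.BoxGridSpec(sizes=(8, 16), n_origins=1)
        assert cb.lacunarity(pat, g, mode="cv_squared") == pytest.approx(1.0)

    def test_empty_pattern_rejected(self):
        with pytest.raises(EmptyPatternError):
            cb.lacunarity(np.zeros((16, 16), dtype=bool), cb.BoxGridSpec(sizes=(2, 4)))

    def test_clustered_exceeds_uniform(self):
        """Spreading a fixed mass uniformly lowers lacunarity (paired seeds)."""
        g = cb.BoxGridSpec(sizes=(4, 8, 16), n_origins=4, seed=0)
        wins = 0
        for s in range(20):
            u = cb.make_point_pattern(400, "uniform", width=64, height=64, seed=s)
            c = cb.make_point_pattern(
                400, "clustered", n_clusters=3, cluster_sd=4.0, width=64, height=64, seed=s
            )
            wins += cb.lacunarity(c, g) > cb.lacunarity(u, g)
        assert wins >= 19  # >= 95% of paired seeds


def test_default_ladder_powers_of_two():
    assert default_sizes((256, 192)) == (2, 4, 8, 16, 32)
    with pytest.raises(InvalidArgumentError):
        default_sizes((10, 10))


def test_branching_ordering_on_synthetic_cohorts():
    """Richer branching: D rises and lacunarity falls at fixed area."""
    import dataclasses

    from cbmorph.preprocess import skeletonize

    base = cb.SyntheticTissueSpec(
        width=128, height=128, n_lobules=8, septum_thickness=10.0,
        branch_density=8.0, branch_length_mean=16.0, seed=33,
    )
    sparse = cb.calibrate_matched_specs(
        dataclasses.replace(base, branch_density=0.0), base,
        tolerance=0.01, n_seeds_coarse=8, n_seeds_fine=16,
    )
    g = cb.BoxGridSpec(sizes=(2, 4, 8, 16), n_origins=3, seed=0)
    ds, lacs = {}, {}
    for name, spec in (("sparse", sparse), ("dense", base)):
        dd, ll = [], []
        for i in range(12):
            _, truth = cb.make_tissue_image(dataclasses.replace(spec, seed=500 + i))
            sk = skeletonize(truth.mask)
            dd.append(cb.fractal_dimension(sk, g).mean_D)
            ll.append(cb.lacunarity(sk, g))
        ds[name], lacs[name] = np.mean(dd), np.mean(ll)
    assert ds["dense"] > ds["sparse"]
    assert lacs["dense"] < lacs["sparse"]
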