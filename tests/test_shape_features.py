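from itertools import combinations

import numpy as np
import pytest

from conftest import blob_from_mask, random_blob, raster_disc
from greenspot.shape_features import (
    FeatureScaler,
    RingProfile,
    SkeletonMask,
    ba_ratio,
    branch_points,
    circularity,
    compute_features,
    max_inscribed_radius,
    min_enclosing_circle,
    point_line_ratio,
    ring_proportions,
    skeletonize,
)


class TestSkeleton:
    def test_thin_line_is_its_own_skeleton(self):
        m = np.zeros((5, 20), dtype=bool)
        m[2, 3:17] = True
        sk = skeletonize(blob_from_mask(m))
        assert sk.length == 14

    def test_rectangle_thins_to_medial_line(self):
        m = np.zeros((7, 15), dtype=bool)
        m[2:5, 2:13] = True
        sk = skeletonize(blob_from_mask(m))
        rows = set(np.nonzero(sk.mask)[0].tolist())
        assert rows <= {0, 1, 2}          # within the 3-row band
        assert 8 <= sk.length <= 12       # roughly the 11-px length

    def test_skeleton_stays_connected(self):
        from skimage.measure import label

        rng = np.random.default_rng(0)
        for _ in range(5):
            b = random_blob(rng)
            sk = skeletonize(b)
            n = label(sk.mask, connectivity=2).max()
            assert n == 1


class TestBranchPoints:
    def test_straight_line_has_none(self):
        m = np.zeros((5, 20), dtype=bool)
        m[2, 2:18] = True
        assert branch_points(SkeletonMask(m, (0, 0, 5, 20)))[0] == 0

    def test_plus_sign_has_one_merged_junction(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, :] = True
        m[:, 5] = True
        n, coords = branch_points(SkeletonMask(m, (0, 0, 11, 11)))
        assert n == 1
        assert tuple(coords[0]) == (5, 5)

    def test_y_shape_has_one_junction(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5:10, 5] = True                       # stem
        for i in range(6):
            m[5 - i, 5 - i] = m[5 - i, 5 + i] = True  # two arms
        assert branch_points(SkeletonMask(m, (0, 0, 11, 11)))[0] == 1


class TestPointLineRatio:
    def test_line_gives_zero(self):
        m = np.zeros((3, 52), dtype=bool)
        m[1, 1:51] = True
        assert point_line_ratio(SkeletonMask(m, (0, 0, 3, 52))) == 0.0

    def test_plus_sign_ratio(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, :] = True
        m[:, 5] = True                          # 21 pixels, one junction
        assert point_line_ratio(SkeletonMask(m, (0, 0, 11, 11))) == pytest.approx(1 / 21)

    def test_invariant_under_quarter_turn(self):
        rng = np.random.default_rng(1)
        b = random_blob(rng)
        rot = blob_from_mask(np.rot90(b.mask))
        assert point_line_ratio(skeletonize(b)) == pytest.approx(
            point_line_ratio(skeletonize(rot)))

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            point_line_ratio(SkeletonMask(np.zeros((3, 3), bool), (0, 0, 3, 3)))


class TestCircularity:
    def test_disc_is_near_one(self):
        assert circularity(blob_from_mask(raster_disc(50))) == pytest.approx(1.0, abs=0.1)

    def test_square_matches_closed_form(self):
        m = np.zeros((60, 60), dtype=bool)
        m[5:55, 5:55] = True
        assert circularity(blob_from_mask(m)) == pytest.approx(np.pi / 4, abs=0.1)

    def test_thin_bar_is_far_from_round(self):
        m = np.zeros((6, 110), dtype=bool)
        m[2:4, 5:105] = True
        assert circularity(blob_from_mask(m)) < 0.15  # closed form ~0.060

    def test_single_pixel_defined_as_one(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert circularity(blob_from_mask(m)) == 1.0


class TestInscribedAndEnclosing:
    def test_disc_radius_recovered(self):
        b = blob_from_mask(raster_disc(30))
        assert max_inscribed_radius(b) == pytest.approx(30, abs=1)
        _, r = min_enclosing_circle(b)
        assert r == pytest.approx(30, abs=1)

    def test_rectangle_half_short_side(self):
        m = np.zeros((30, 50), dtype=bool)
        m[5:25, 5:45] = True
        assert max_inscribed_radius(blob_from_mask(m)) == pytest.approx(10, abs=1)

    def test_two_pixels_span(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 2] = m[2, 8] = True
        (cy, cx), r = min_enclosing_circle(blob_from_mask(m))
        assert (cy, cx) == pytest.approx((2.0, 5.0))
        assert r == pytest.approx(3.0)

    @staticmethod
    def mec_bruteforce(pts):
        """Exact oracle: best circle through every pair and triple."""

        def circ3(a, b, c):
            (ay, ax), (by, bx), (cy, cx) = a, b, c
            d = 2 * (ay * (bx - cx) + by * (cx - ax) + cy * (ax - bx))
            if abs(d) < 1e-12:
                return None
            uy = ((ay**2 + ax**2) * (bx - cx) + (by**2 + bx**2) * (cx - ax)
                  + (cy**2 + cx**2) * (ax - bx)) / d
            ux = ((ay**2 + ax**2) * (cy - by) + (by**2 + bx**2) * (ay - cy)
                  + (cy**2 + cx**2) * (by - ay)) / d
            ctr = np.array([uy, ux])
            return ctr, np.linalg.norm(a - ctr)

        best = None
        for a, b in combinations(pts, 2):
            ctr = (a + b) / 2
            r = np.linalg.norm(a - ctr)
            if all(np.linalg.norm(p - ctr) <= r + 1e-9 for p in pts):
                if best is None or r < best[1]:
                    best = (ctr, r)
        for a, b, c in combinations(pts, 3):
            res = circ3(a, b, c)
            if res and all(np.linalg.norm(p - res[0]) <= res[1] + 1e-9 for p in pts):
                if best is None or res[1] < best[1]:
                    best = res
        return best

    def test_near_equilateral_triangle_circumradius(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0, 0] = m[0, 8] = m[7, 4] = True
        (cy, cx), r = min_enclosing_circle(blob_from_mask(m))
        ctr, r_ref = self.mec_bruteforce(np.array([[0, 0], [0, 8], [7, 4]], float))
        assert (cy, cx) == pytest.approx(tuple(ctr))
        assert r == pytest.approx(r_ref)
        # sanity: near the analytic circumradius a/sqrt(3) for side ~8
        assert r == pytest.approx(8 / np.sqrt(3), rel=0.02)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_point_sets(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 25, (int(rng.integers(3, 10)), 2)).astype(float)
        m = np.zeros((25, 25), dtype=bool)
        m[pts[:, 0].astype(int), pts[:, 1].astype(int)] = True
        _, r = min_enclosing_circle(blob_from_mask(m))
        uniq = np.unique(m.nonzero()[0] * 25 + m.nonzero()[1])  # noqa: F841
        pts_uniq = np.argwhere(m).astype(float)
        _, r_ref = self.mec_bruteforce(pts_uniq)
        assert r == pytest.approx(r_ref, abs=1e-9)

    def test_inscribed_never_exceeds_enclosing(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            b = random_blob(rng)
            _, r = min_enclosing_circle(b)
            assert max_inscribed_radius(b) <= r + 1.0  # +1 px discretization


def ring_bruteforce(blob, center, r, n_rings=8):
    """Per-pixel distance counting, written independently of the module path."""
    cy, cx = center
    counts_fg = [0] * n_rings
    counts_all = [0] * n_rings
    fg = {(int(p[0]), int(p[1])) for p in blob.pixels}
    for row in range(int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1):
        for col in range(int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1):
            d = np.hypot(row - cy, col - cx)
            for k in range(1, n_rings + 1):
                if (k - 1) * r / n_rings < d <= k * r / n_rings:
                    counts_all[k - 1] += 1
                    if (row, col) in fg:
                        counts_fg[k - 1] += 1
                    break
    return np.array([f / a if a else 0.0 for f, a in zip(counts_fg, counts_all)])


class TestRingProfile:
    def test_solid_disc_fills_every_ring(self):
        b = blob_from_mask(raster_disc(40))
        prof = ring_proportions(b, b.centroid, 40.0)
        assert np.all(prof.proportions > 0.9)

    def test_outer_annulus_occupies_last_ring_only(self):
        n = 81
        yy, xx = np.mgrid[:n, :n]
        d = np.hypot(yy - 40, xx - 40)
        m = (d <= 40) & (d > 35)
        b = blob_from_mask(m)
        prof = ring_proportions(b, (40.0, 40.0), 40.0)
        assert prof.proportions[7] > 0.85
        assert np.all(prof.proportions[:6] < 0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_exactly(self, seed):
        rng = np.random.default_rng(seed)
        b = random_blob(rng)
        _, r = min_enclosing_circle(b)
        prof = ring_proportions(b, b.centroid, max(r, 1.0))
        ref = ring_bruteforce(b, b.centroid, max(r, 1.0))
        assert np.array_equal(prof.proportions, ref)

    def test_zero_radius_rejected(self):
        b = blob_from_mask(raster_disc(5))
        with pytest.raises(ValueError):
            ring_proportions(b, b.centroid, 0.0)


class TestQuadraticFit:
    def test_pure_square_term(self):
        k = np.arange(1, 9)
        prof = RingProfile(center=(0, 0), r=8.0, proportions=(k**2) / 64.0)
        a, b, c, ratio = ba_ratio(prof)
        assert a == pytest.approx(1 / 64)
        assert b == pytest.approx(0, abs=1e-9)
        assert ratio == pytest.approx(0, abs=1e-6)

    def test_known_polynomial_ratio(self):
        k = np.arange(1, 9)
        prof = RingProfile(center=(0, 0), r=8.0,
                           proportions=(2 * k**2 + 4 * k + 1) / 200.0)
        *_, ratio = ba_ratio(prof)
        assert ratio == pytest.approx(2.0)

    def test_constant_profile_clamps(self):
        prof = RingProfile(center=(0, 0), r=8.0, proportions=np.full(8, 0.5))
        a, b, c, ratio = ba_ratio(prof)
        assert abs(a) < 1e-6
        assert ratio == pytest.approx(0, abs=1e-6) or abs(ratio) == pytest.approx(1e6)

    def test_too_few_rings_rejected(self):
        prof = RingProfile(center=(0, 0), r=2.0, proportions=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            ba_ratio(prof)


class TestComposite:
    def test_translation_invariance_is_exact(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:15, 5:20] = True
        m[8:12, 18:25] = True
        f1 = compute_features(blob_from_mask(m))
        f2 = compute_features(blob_from_mask(m, offset=(100, 200)))
        assert f1 == f2

    def test_disc_is_round_with_flat_profile(self):
        f = compute_features(blob_from_mask(raster_disc(40)))
        assert f.rod == pytest.approx(1.0, abs=0.1)
        assert abs(f.a) < 0.01  # near-flat ring profile

    def test_rosette_branchier_than_single_stem(self):
        from greenspot.synthgen import PlantSpec, gen_cabbage, gen_weed, rng_for

        cab_mask, _, _ = gen_cabbage(PlantSpec("cabbage"), rng_for(0, "c"))
        weed_mask, _, _ = gen_weed(PlantSpec("descurainia-like"), rng_for(0, "w"))
        f_cab = compute_features(blob_from_mask(cab_mask))
        f_weed = compute_features(blob_from_mask(weed_mask))
        assert f_cab.rat_i_l > f_weed.rat_i_l

    def test_isotropic_scaling_moves_radii_not_shape(self):
        small = compute_features(blob_from_mask(raster_disc(20)))
        big = compute_features(blob_from_mask(raster_disc(40)))
        assert big.r_inscribed == pytest.approx(2 * small.r_inscribed, rel=0.1)
        assert big.r_enclosing == pytest.approx(2 * small.r_enclosing, rel=0.1)
        assert big.rod == pytest.approx(small.rod, abs=0.05)


class TestScaler:
    def test_midpoint_maps_to_half(self):
        X = np.array([[2.0], [10.0]])
        s = FeatureScaler.fit(X)
        assert s.transform(np.array([[6.0]]))[0, 0] == pytest.approx(0.5)

    def test_out_of_range_clamps(self):
        s = FeatureScaler.fit(np.array([[2.0], [10.0]]))
        assert s.transform(np.array([[0.0]]))[0, 0] == 0.0
        assert s.transform(np.array([[99.0]]))[0, 0] == 1.0

    def test_training_extremes_map_to_unit_interval(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        s = FeatureScaler.fit(X)
        Z = s.transform(X)
        assert np.allclose(Z.min(axis=0), 0.0)
        assert np.allclose(Z.max(axis=0), 1.0)

    def test_constant_feature_maps_to_half(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        s = FeatureScaler.fit(X)
        assert np.all(s.transform(X)[:, 1] == 0.5)
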