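"""Shape analysis: contour, curvature, thinning skeleton, endpoints,
head/tail candidates and morphometrics."""

import numpy as np
import pytest

from sostrack import posture as pm
from sostrack.errors import BranchedSkeletonError, NoObjectError, SosError

from conftest import circle_contour, make_capsule
from oracles import boundary_trace_oracle, thinning_oracle


def rect_mask(h=4, w=10, pad=3):
    m = np.zeros((h + 2 * pad, w + 2 * pad), bool)
    m[pad:pad + h, pad:pad + w] = True
    return m


def disk_mask(r=8, pad=3):
    size = 2 * (r + pad) + 1
    yy, xx = np.ogrid[:size, :size]
    return (yy - r - pad) ** 2 + (xx - r - pad) ** 2 <= r * r


class TestExtractContour:
    def test_rectangle_perimeter_close_to_boundary_trace(self):
        m = rect_mask(4, 10)
        contour = pm.extract_contour(m)
        per = np.linalg.norm(np.diff(np.vstack([contour, contour[:1]]), axis=0),
                             axis=1).sum()
        assert abs(per - 28.0) / 28.0 < 0.10
        # and within 20% of the Moore boundary walk over pixel centres
        oracle = boundary_trace_oracle(m)
        assert abs(per - oracle) / oracle < 0.20

    def test_interior_hole_is_filled(self):
        m = rect_mask(8, 8)
        holed = m.copy()
        holed[6:8, 6:8] = False
        assert np.allclose(sorted(pm.extract_contour(holed).ravel()),
                           sorted(pm.extract_contour(m).ravel()))

    def test_single_pixel_degenerate(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        contour = pm.extract_contour(m)
        assert len(contour) >= 3          # tiny diamond around the pixel

    def test_empty_mask_raises(self):
        with pytest.raises(NoObjectError):
            pm.extract_contour(np.zeros((4, 4), bool))

    def test_orientation_normalized_positive_area(self):
        contour = pm.extract_contour(disk_mask(6))
        x, y = contour[:, 0], contour[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0


class TestSmoothContour:
    def test_window_one_is_identity(self):
        c = circle_contour(20)
        assert np.array_equal(pm.smooth_contour(c, 1), c)

    def test_circle_stays_circular(self):
        c = circle_contour(50)
        s = pm.smooth_contour(c, 5)
        radii = np.linalg.norm(s, axis=1)
        assert np.max(np.abs(radii - 50)) <= 1.0

    def test_point_count_preserved_and_cyclic(self):
        c = circle_contour(10, n=40)
        s = pm.smooth_contour(c, 7)
        assert len(s) == 40
        # cyclic smoothing: rotating the input rotates the output
        rolled = pm.smooth_contour(np.roll(c, 13, axis=0), 7)
        assert np.allclose(np.roll(s, 13, axis=0), rolled)

    def test_window_larger_than_contour_raises(self):
        with pytest.raises(SosError):
            pm.smooth_contour(circle_contour(5, n=10), 11)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pm.smooth_contour(circle_contour(5), 4)


class TestSkeletonize:
    def test_bar_thins_to_path_with_two_endpoints(self):
        skel = pm.skeletonize(rect_mask(3, 11))
        endpoints, spur = pm.skeleton_endpoints(skel)
        assert not spur and len(endpoints) == 2
        assert skel.sum() == thinning_oracle(rect_mask(3, 11)).sum()

    def test_disk_collapses_to_blob_core(self):
        skel = pm.skeletonize(disk_mask(8))
        assert skel.sum() <= 3

    def test_l_band_connected_with_two_endpoints(self):
        m = np.zeros((22, 22), bool)
        m[3:17, 3:6] = True
        m[14:17, 3:17] = True
        skel = pm.skeletonize(m)
        endpoints, spur = pm.skeleton_endpoints(skel)
        assert len(endpoints) == 2 and not spur

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_thinning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((28, 28), bool)
        r0, c0 = rng.integers(2, 8, 2)
        h, w = rng.integers(3, 14, 2)
        m[r0:r0 + h, c0:c0 + w] = True
        if seed % 3 == 0:
            m[r0:r0 + 3, c0:c0 + 16] = True
        if seed % 4 == 0:
            yy, xx = np.ogrid[:28, :28]
            m |= (yy - 16) ** 2 + (xx - 16) ** 2 <= int(rng.integers(4, 40))
        assert np.array_equal(pm.skeletonize(m), thinning_oracle(m))

    def test_skeleton_inside_mask(self):
        crop, _ = make_capsule(bend_deg=60, seed=1)
        assert not (pm.skeletonize(crop) & ~crop).any()


class TestSkeletonEndpoints:
    def test_straight_path(self):
        skel = np.zeros((5, 9), bool)
        skel[2, 1:8] = True
        endpoints, spur = pm.skeleton_endpoints(skel)
        assert len(endpoints) == 2 and not spur

    def test_y_shape_flags_spur(self):
        skel = np.zeros((9, 9), bool)
        skel[4, 0:5] = True
        skel[0:4, 4] = True
        skel[5:9, 4] = True
        endpoints, spur = pm.skeleton_endpoints(skel)
        assert len(endpoints) == 3 and spur

    def test_isolated_pixel_is_endpoint(self):
        skel = np.zeros((3, 3), bool)
        skel[1, 1] = True
        endpoints, spur = pm.skeleton_endpoints(skel)
        assert len(endpoints) == 1 and spur


class TestContourCurvature:
    @pytest.mark.parametrize("radius", [20, 50, 100])
    def test_circle_curvature_is_one_over_r(self, radius):
        k = pm.contour_curvature(circle_contour(radius))
        assert np.all(np.abs(k * radius - 1) < 0.15)

    def test_straight_edge_near_zero(self):
        c = circle_contour(200)
        k = pm.contour_curvature(c, arc_window=5)
        assert np.all(np.abs(k) <= 0.006)

    def test_capsule_maxima_at_cap_tips(self):
        # the global maximum sits on one cap; the best point at least a
        # quarter of the contour away sits on the other
        crop, info = make_capsule(seed=3)
        contour = pm.smooth_contour(pm.extract_contour(crop), 5)
        k = pm.contour_curvature(contour)
        n = len(contour)
        i0 = int(np.argmax(k))
        far = [i for i in range(n) if n // 4 <= (i - i0) % n <= 3 * n // 4]
        i1 = far[int(np.argmax(k[far]))]
        picked = contour[[i0, i1]]
        for tip in (info["apex_head_px"], info["apex_tail_px"]):
            assert min(np.linalg.norm(picked - tip, axis=1)) < 3.0

    def test_too_short_contour_raises(self):
        with pytest.raises(SosError):
            pm.contour_curvature(circle_contour(2, n=5), arc_window=10)


class TestHeadTailCandidates:
    def test_capsule_candidates_are_cap_tips(self):
        crop, info = make_capsule(seed=5)
        contour = pm.smooth_contour(pm.extract_contour(crop), 5)
        k = pm.contour_curvature(contour)
        a, b, blob = pm.head_tail_candidates(contour, k)
        assert not blob
        errs = sorted([
            min(np.linalg.norm(a - info["apex_head_px"]),
                np.linalg.norm(b - info["apex_head_px"])),
            min(np.linalg.norm(a - info["apex_tail_px"]),
                np.linalg.norm(b - info["apex_tail_px"]))])
        assert errs[-1] < 3.0

    def test_circle_flagged_blob_like(self):
        contour = pm.extract_contour(disk_mask(15))
        k = pm.contour_curvature(contour)
        _, _, blob = pm.head_tail_candidates(contour, k)
        assert blob

    def test_bent_capsule_still_finds_tips_not_bend(self):
        crop, info = make_capsule(bend_deg=100, seed=7)
        contour = pm.smooth_contour(pm.extract_contour(crop), 5)
        k = pm.contour_curvature(contour)
        a, b, blob = pm.head_tail_candidates(contour, k)
        assert not blob
        for cand in (a, b):
            d = min(np.linalg.norm(cand - info["apex_head_px"]),
                    np.linalg.norm(cand - info["apex_tail_px"]))
            assert d < 3.0


class TestOrderSkeleton:
    def test_orders_left_to_right_from_head(self):
        skel = np.zeros((5, 9), bool)
        skel[2, 1:8] = True
        path = pm.order_skeleton(skel, np.array([1, 2]))
        assert np.array_equal(path[0], [1, 2]) and np.array_equal(path[-1], [7, 2])

    def test_reversed_with_head_at_other_end(self):
        skel = np.zeros((5, 9), bool)
        skel[2, 1:8] = True
        path = pm.order_skeleton(skel, np.array([7, 2]))
        assert np.array_equal(path[0], [7, 2]) and np.array_equal(path[-1], [1, 2])

    def test_branched_skeleton_raises(self):
        skel = np.zeros((9, 9), bool)
        skel[4, 0:5] = True
        skel[0:4, 4] = True
        skel[5:9, 4] = True
        with pytest.raises(BranchedSkeletonError):
            pm.order_skeleton(skel, np.array([0, 4]))

    def test_path_visits_every_pixel_once(self):
        crop, _ = make_capsule(bend_deg=45, seed=11)
        skel = pm.skeletonize(crop)
        endpoints, _ = pm.skeleton_endpoints(skel)
        path = pm.order_skeleton(skel, endpoints[0])
        assert len(path) == skel.sum()
        assert len({tuple(p) for p in path.astype(int)}) == len(path)


class TestPostureMetrics:
    def test_rectangle_area_and_centroid(self):
        m = rect_mask(4, 10, pad=3)
        contour = pm.extract_contour(m)
        skel = pm.skeletonize(m)
        endpoints, _ = pm.skeleton_endpoints(skel)
        path = pm.order_skeleton(skel, endpoints[0])
        area, per, slen, centroid, midpoint = pm.posture_metrics(m, contour, path)
        assert area == 40
        assert np.allclose(centroid, [3 + 4.5, 3 + 1.5])

    def test_bar_skeleton_length_matches_thinning_oracle(self):
        m = rect_mask(3, 11)
        oracle_path = thinning_oracle(m)
        skel = pm.skeletonize(m)
        endpoints, _ = pm.skeleton_endpoints(skel)
        path = pm.order_skeleton(skel, endpoints[0])
        _, _, slen, _, _ = pm.posture_metrics(m, pm.extract_contour(m), path)
        assert slen == oracle_path.sum() - 1      # unit steps on a straight path

    def test_capsule_midpoint_near_midline_center(self):
        crop, info = make_capsule(seed=13)
        p = pm.analyze_mask(crop, smooth_px=0)
        center = info["midline_px"][len(info["midline_px"]) // 2]
        assert np.linalg.norm(p.midpoint - center) < 2.0


class TestAnalyzeMaskAndQc:
    def test_straight_capsule_unflagged(self):
        crop, info = make_capsule(seed=17)
        p = pm.analyze_mask(crop)
        assert p.flags == set()
        assert abs(p.skeleton_length - info["length_px"]) / info["length_px"] < 0.10

    def test_disk_flagged_blob_like(self):
        p = pm.analyze_mask(disk_mask(8))
        assert "blob_like" in p.flags

    def test_random_curved_postures_quality(self):
        # endpoints, tip accuracy and skeleton length across 60 random poses
        n_two = 0
        errs = []
        for seed in range(60):
            bend = float(np.random.default_rng(seed).uniform(-100, 100))
            crop, info = make_capsule(bend_deg=bend, seed=seed, mpp=0.08)
            # noise-free masks need no morphological pre-smoothing
            p = pm.analyze_mask(crop, smooth_px=0)
            if len(p.endpoints) == 2:
                n_two += 1
                for gt in (info["head_px"], info["tail_px"]):
                    errs.append(min(np.linalg.norm(p.head - gt),
                                    np.linalg.norm(p.tail - gt)))
                assert abs(p.skeleton_length - info["length_px"]) \
                    / info["length_px"] < 0.10
        assert n_two >= 0.95 * 60
        assert np.quantile(errs, 0.99) <= 3.0

    def test_qc_summary_fractions(self):
        crop, _ = make_capsule(seed=1)
        good = pm.analyze_mask(crop)
        flagged = pm.analyze_mask(crop)
        flagged.flags.add("spur")
        discarded = pm.analyze_mask(crop)
        discarded.flags.add("discarded")
        postures = [good] * 97 + [flagged] * 2 + [discarded]
        qc = pm.qc_summary(postures)
        assert qc["fraction_spur"] == 0.02
        assert qc["fraction_discarded"] == 0.01
        assert pm.qc_summary([good]) == {
            "fraction_spur": 0.0, "fraction_blob_like": 0.0,
            "fraction_discarded": 0.0}

    def test_qc_empty_raises(self):
        with pytest.raises(SosError):
            pm.qc_summary([])

    def test_head_and_tail_near_contour(self):
        crop, _ = make_capsule(bend_deg=30, seed=19)
        p = pm.analyze_mask(crop)
        for pt in (p.head, p.tail):
            assert np.min(np.linalg.norm(p.contour - pt, axis=1)) <= \
                2 + 0.25 / 0.05       # within the cap of the smoothed contour

    def test_translate_shifts_all_coordinates(self):
        crop, _ = make_capsule(seed=23)
        p = pm.analyze_mask(crop)
        q = pm.translate(p, (10.0, 20.0))
        assert np.allclose(q.head, p.head + [10, 20])
        assert np.allclose(q.contour, p.contour + [10, 20])
        assert q.area == p.area
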