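"""Shell extraction, curve regions, eccentricity, classification, merging."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spherecut import (
    Aggregate,
    IntersectionCurve,
    Scene,
    SpheroidFruit,
    LeafPatch,
    Thresholds,
    circle_radius,
    classify_region,
    cluster_aggregates,
    curve_regions,
    depth_window,
    extract_shell,
    frame_to_points,
    merge_detections,
    region_eccentricity,
    render_depth,
    single_cut,
    successive_cut,
)
from spherecut.detect import anchor_radius

from test_cloud import make_cloud


def sphere_aggregate(clean_f200, center=(0.0, 0.0, 400.0), d=55.0):
    scene = Scene([SpheroidFruit(list(center), d, d)], clean_f200)
    frame, _ = render_depth(scene, 0)
    cloud = frame_to_points(depth_window(frame), clean_f200)
    aggs = cluster_aggregates(cloud, 10.0)
    return max(aggs, key=lambda a: a.count)


class TestExtractShell:
    def test_beyond_farthest_point_is_empty(self):
        cloud = make_cloud([0, 0, 1], [0, 1, 0], [300.0, 305.0, 310.0])
        agg = Aggregate(cloud, np.arange(3), id=0)
        assert len(extract_shell(agg, 400.0, 1.5)) == 0

    def test_wide_shell_keeps_everything(self):
        cloud = make_cloud([0, 0, 1], [0, 1, 0], [300.0, 305.0, 310.0])
        agg = Aggregate(cloud, np.arange(3), id=0)
        assert len(extract_shell(agg, 305.0, 6.0)) == 3

    def test_ring_radius_matches_cut_geometry(self, clean_f200):
        """The extracted ring's mean angular radius equals asin(RC'/RC)."""
        agg = sphere_aggregate(clean_f200)
        RA = anchor_radius(agg)
        RC = RA + 5.0
        shell = extract_shell(agg, RC, 1.0)
        assert len(shell) > 50
        rows = shell.rows - shell.rows.mean()
        cols = shell.cols - shell.cols.mean()
        mean_radius_px = np.hypot(
            rows / clean_f200.ppr_v, cols / clean_f200.ppr_h
        ).mean() * clean_f200.ppr_h
        want_px = math.asin(circle_radius(27.5, RA, 5.0) / RC) * clean_f200.ppr_h
        assert mean_radius_px == pytest.approx(want_px, rel=0.10)

    def test_rejects_bad_parameters(self):
        cloud = make_cloud([0], [0], [300.0])
        agg = Aggregate(cloud, np.arange(1), id=0)
        with pytest.raises(ValueError):
            extract_shell(agg, -1.0, 1.0)


def flood_fill_oracle(pixels):
    """BFS 8-connected components of a pixel set."""
    todo = set(map(tuple, pixels))
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            r, c = queue.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in todo:
                        todo.remove(nb)
                        comp.add(nb)
                        queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestCurveRegions:
    def test_empty_shell(self):
        assert curve_regions(make_cloud([], [], [])) == []

    def test_two_separated_rings(self):
        pix = []
        for ang in np.linspace(0, 2 * math.pi, 60, endpoint=False):
            pix.append((int(20 + 8 * math.sin(ang)), int(20 + 8 * math.cos(ang))))
            pix.append((int(20 + 8 * math.sin(ang)), int(60 + 8 * math.cos(ang))))
        pix = sorted(set(pix))
        rows = np.array([p[0] for p in pix])
        cols = np.array([p[1] for p in pix])
        cloud = make_cloud(rows, cols, np.full(rows.size, 300.0))
        assert len(curve_regions(cloud)) == 2

    def test_membership_matches_flood_fill(self):
        rng = np.random.default_rng(6)
        pix = sorted({(int(a), int(b)) for a, b in rng.integers(0, 25, size=(150, 2))})
        rows = np.array([p[0] for p in pix])
        cols = np.array([p[1] for p in pix])
        cloud = make_cloud(rows, cols, np.full(rows.size, 300.0))
        got = {frozenset(map(tuple, c.pixels.tolist())) for c in curve_regions(cloud)}
        assert got == flood_fill_oracle(pix)

    def test_center3d_is_mean_of_members(self):
        cloud = make_cloud([0, 0], [0, 1], [300.0, 302.0])
        (curve,) = curve_regions(cloud)
        np.testing.assert_allclose(curve.center3d, [[0, 0, 301.0]][0])


class TestEccentricity:
    def test_filled_disc_is_nearly_circular(self):
        yy, xx = np.mgrid[-20:21, -20:21]
        pix = np.column_stack(np.nonzero(xx * xx + yy * yy <= 400))
        assert region_eccentricity(pix) < 0.1

    def test_pixel_line_is_nearly_one(self):
        pix = [(0, c) for c in range(50)]
        assert region_eccentricity(pix) > 0.99

    def test_two_to_one_ellipse(self):
        yy, xx = np.mgrid[-25:26, -45:46]
        pix = np.column_stack(np.nonzero((xx / 40.0) ** 2 + (yy / 20.0) ** 2 <= 1))
        assert region_eccentricity(pix) == pytest.approx(0.866, abs=0.02)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(10)
        pix = rng.integers(0, 30, size=(80, 2))
        base = region_eccentricity(pix)
        assert region_eccentricity(pix + [7, 11]) == pytest.approx(base, abs=1e-12)
        rotated = np.column_stack([pix[:, 1], -pix[:, 0]])  # 90 degrees
        assert region_eccentricity(rotated) == pytest.approx(base, abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40)),
                    min_size=1, max_size=60, unique=True))
    def test_bounded_in_unit_interval(self, pix):
        assert 0.0 <= region_eccentricity(pix) <= 1.0

    def test_single_pixel_is_zero(self):
        assert region_eccentricity([(5, 9)]) == 0.0

    def test_agrees_with_skimage_on_random_blobs(self):
        skimage = pytest.importorskip("skimage.measure")
        rng = np.random.default_rng(14)
        for _ in range(10):
            img = np.zeros((40, 40), dtype=int)
            r0, c0 = rng.integers(5, 20, 2)
            img[r0:r0 + rng.integers(3, 15), c0:c0 + rng.integers(3, 15)] = 1
            props = skimage.regionprops(img)[0]
            pix = np.column_stack(np.nonzero(img))
            assert region_eccentricity(pix) == pytest.approx(
                props.eccentricity, abs=1e-6
            )


class TestClassification:
    def _curve(self, E, AN):
        return IntersectionCurve(
            pixels=np.zeros((AN, 2), dtype=int), AN=AN, E=E, centroid=(0.0, 0.0),
            cut_radius=300.0, source_id=0, center3d=np.zeros(3),
        )

    def test_round_fruit_like_region_accepted(self):
        assert classify_region(self._curve(0.2, 400), 0.85, 60) == "fruit_candidate"

    def test_leaf_like_arc_rejected_by_eccentricity(self):
        assert classify_region(self._curve(0.95, 4000), 0.85, 60) == "rejected"

    def test_small_region_rejected_by_count(self):
        assert classify_region(self._curve(0.1, 10), 0.85, 60) == "rejected"


class TestCuts:
    def test_successive_cut_on_sphere_yields_candidates(self, clean_f200):
        agg = sphere_aggregate(clean_f200)
        agg.kind = "adherent"
        candidates = successive_cut(agg, Thresholds())
        assert len(candidates) >= 1
        assert all(c.cut_depth is not None for c in candidates)

    def test_flat_leaf_yields_no_candidates(self, clean_f200):
        scene = Scene(
            [LeafPatch([0.0, 0.0, 350.0], 55.0, 30.0,
                       [math.sin(0.6), 0.0, -math.cos(0.6)])],
            clean_f200,
        )
        frame, _ = render_depth(scene, 0)
        cloud = frame_to_points(depth_window(frame), clean_f200)
        agg = max(cluster_aggregates(cloud, 10.0), key=lambda a: a.count)
        assert successive_cut(agg, Thresholds()) == []

    def test_empty_schedule_is_empty(self, clean_f200):
        agg = sphere_aggregate(clean_f200)
        t = Thresholds(L_start=10.0, L_step=2.0, L_max=4.0)
        assert successive_cut(agg, t) == []

    def test_single_cut_matches_anchor(self, clean_f200):
        agg = sphere_aggregate(clean_f200)
        candidates = single_cut(agg, Thresholds(), 5.0)
        assert len(candidates) == 1
        assert candidates[0].cut_radius == pytest.approx(anchor_radius(agg) + 5.0)

    def test_anchor_matches_closest_point_without_noise(self, clean_f200):
        from spherecut import closest_point

        agg = sphere_aggregate(clean_f200)
        assert anchor_radius(agg) == pytest.approx(closest_point(agg).r, abs=0.05)


class TestMerge:
    def _ring(self, center, AN=200, L=4.0):
        return IntersectionCurve(
            pixels=np.zeros((AN, 2), dtype=int), AN=AN, E=0.2, centroid=(0.0, 0.0),
            cut_radius=float(np.linalg.norm(center)), source_id=0,
            center3d=np.asarray(center, dtype=float), cut_depth=L,
        )

    def test_concentric_rings_merge_to_one(self):
        a = self._ring([0.0, 0.0, 380.0])
        b = self._ring([0.5, -0.3, 383.0])
        dets = merge_detections([a, b], merge_radius=19.6)
        assert len(dets) == 1
        assert dets[0].total_AN == 400

    def test_distant_rings_stay_separate(self):
        a = self._ring([0.0, 0.0, 380.0])
        b = self._ring([120.0, 0.0, 380.0])
        dets = merge_detections([a, b], merge_radius=30.0)
        assert len(dets) == 2
        # ordered by closest member depth
        assert np.linalg.norm(dets[0].center) <= np.linalg.norm(dets[1].center)

    def test_empty_input(self):
        assert merge_detections([], 20.0) == []

    def test_weighted_center(self):
        a = self._ring([0.0, 0.0, 300.0], AN=100)
        b = self._ring([0.0, 0.0, 310.0], AN=300)
        (det,) = merge_detections([a, b], merge_radius=20.0)
        assert det.center[2] == pytest.approx(307.5)

    def test_fruit_radius_push_recovers_sphere_center(self, clean_f200):
        agg = sphere_aggregate(clean_f200)
        (curve,) = single_cut(agg, Thresholds(), 5.0)
        (det,) = merge_detections([curve], 19.6, fruit_radius=27.5)
        assert np.linalg.norm(det.center - [0.0, 0.0, 400.0]) < 2.0
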