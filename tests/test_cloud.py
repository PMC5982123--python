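"""Point-cloud lifting, clustering and aggregate labelling."""

import numpy as np
import pytest

from spherecut import (
    DepthFrame,
    PointCloud,
    Scene,
    SpheroidFruit,
    closest_point,
    cluster_aggregates,
    filter_branches,
    frame_to_points,
    make_sensor,
    render_depth,
    split_isolated_adherent,
)
from spherecut.cloud import footprint_moments

from conftest import oracle_pixel_depth


def make_cloud(rows, cols, r, sensor=None):
    """Synthetic cloud with given pixel coordinates and radial distances."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    r = np.asarray(r, dtype=float)
    zeros = np.zeros_like(r)
    return PointCloud(rows, cols, r, zeros, zeros, zeros, zeros, r, sensor)


class TestFrameToPoints:
    def test_all_invalid_frame_gives_empty_cloud(self, f200):
        cloud = frame_to_points(DepthFrame(np.zeros(f200.shape)), f200)
        assert len(cloud) == 0

    def test_center_pixel_is_on_axis(self, f200):
        vals = np.zeros(f200.shape)
        vals[f200.n // 2, f200.m // 2] = 300.0
        cloud = frame_to_points(DepthFrame(vals), f200)
        p = cloud.point(0)
        assert abs(p.theta) < f200.theta0 / f200.m
        assert abs(p.phi) < f200.phi0 / f200.n
        assert p.r == pytest.approx(300.0, abs=0.01)
        assert p.r >= p.z

    def test_dimension_mismatch_rejected(self, f200):
        with pytest.raises(ValueError):
            frame_to_points(DepthFrame(np.zeros((3, 3))), f200)

    def test_radial_distance_matches_ray_cast_oracle(self, tiny_sensor):
        """Every r of a rendered noise-free sphere equals the analytic
        ray-sphere distance along that pixel's ray."""
        scene = Scene(
            [SpheroidFruit([15.0, -10.0, 380.0], 52.0, 58.0, [0.3, 0.9, 0.2])],
            tiny_sensor,
        )
        frame, _ = render_depth(scene, 0)
        cloud = frame_to_points(frame, tiny_sensor)
        assert len(cloud) > 0
        for k in range(len(cloud)):
            p = cloud.point(k)
            z_true = oracle_pixel_depth(scene, p.row, p.col)
            d = np.array([np.tan(p.theta), np.tan(p.phi), 1.0])
            r_true = z_true * np.linalg.norm(d)
            assert p.r == pytest.approx(r_true, abs=1e-6)


class TestClosestPoint:
    def test_single_point(self):
        cloud = make_cloud([3], [4], [250.0])
        assert closest_point(cloud).r == 250.0

    def test_minimum_of_three(self):
        cloud = make_cloud([0, 1, 2], [0, 1, 2], [305.0, 290.0, 400.0])
        p = closest_point(cloud)
        assert (p.row, p.col, p.r) == (1, 1, 290.0)

    def test_ties_break_on_row_then_col(self):
        cloud = make_cloud([5, 2, 2], [1, 9, 3], [100.0, 100.0, 100.0])
        p = closest_point(cloud)
        assert (p.row, p.col) == (2, 3)

    def test_matches_linear_scan_on_large_cloud(self):
        rng = np.random.default_rng(8)
        n = 10_000
        rows = rng.integers(0, 480, n)
        cols = rng.integers(0, 640, n)
        r = rng.uniform(160, 700, n)
        cloud = make_cloud(rows, cols, r)
        assert closest_point(cloud).r == r.min()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            closest_point(make_cloud([], [], []))


def union_find_oracle(cloud, link_tau):
    """Quadratic-time reference clustering over all point pairs."""
    n = len(cloud)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    rows, cols, r = cloud.rows, cloud.cols, cloud.r
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    drad = np.abs(r[:, None] - r[None, :])
    linked = (dr <= 1) & (dc <= 1) & (drad <= link_tau)
    for a, b in zip(*np.nonzero(np.triu(linked, k=1))):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    groups = {}
    for k in range(n):
        groups.setdefault(find(k), set()).add((int(rows[k]), int(cols[k])))
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_empty_cloud(self):
        assert cluster_aggregates(make_cloud([], [], [])) == []

    def test_single_rendered_sphere_is_one_aggregate(self, axis_sphere_scene):
        frame, _ = render_depth(axis_sphere_scene, 0)
        cloud = frame_to_points(frame, axis_sphere_scene.sensor)
        aggs = cluster_aggregates(cloud, 10.0)
        assert len(aggs) == 1
        assert aggs[0].count == len(cloud)

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(4)
        n = 2000
        rows = rng.integers(0, 60, n)
        cols = rng.integers(0, 80, n)
        # unique pixels with random radial distances in two depth bands
        seen = {}
        for k in range(n):
            seen[(int(rows[k]), int(cols[k]))] = rng.uniform(200, 230) + (
                200 if rng.random() < 0.3 else 0
            )
        rows = np.array([p[0] for p in seen])
        cols = np.array([p[1] for p in seen])
        r = np.array(list(seen.values()))
        cloud = make_cloud(rows, cols, r)
        got = {
            frozenset(zip(a.rows.tolist(), a.cols.tolist()))
            for a in cluster_aggregates(cloud, 10.0)
        }
        assert got == union_find_oracle(cloud, 10.0)

    def test_partition_covers_all_points_once(self):
        rng = np.random.default_rng(9)
        seen = {(int(a), int(b)): rng.uniform(200, 600)
                for a, b in rng.integers(0, 40, size=(800, 2))}
        rows = np.array([p[0] for p in seen])
        cols = np.array([p[1] for p in seen])
        cloud = make_cloud(rows, cols, np.array(list(seen.values())))
        aggs = cluster_aggregates(cloud, 10.0)
        counts = sum(a.count for a in aggs)
        assert counts == len(cloud)
        pixels = [px for a in aggs for px in a.pixel_footprint]
        assert len(set(pixels)) == len(pixels) == len(cloud)

    def test_invariant_to_enumeration_order(self):
        rng = np.random.default_rng(13)
        seen = {(int(a), int(b)): rng.uniform(200, 600)
                for a, b in rng.integers(0, 30, size=(300, 2))}
        rows = np.array([p[0] for p in seen])
        cols = np.array([p[1] for p in seen])
        r = np.array(list(seen.values()))
        perm = rng.permutation(len(rows))
        sets1 = {
            frozenset(zip(a.rows.tolist(), a.cols.tolist()))
            for a in cluster_aggregates(make_cloud(rows, cols, r), 10.0)
        }
        sets2 = {
            frozenset(zip(a.rows.tolist(), a.cols.tolist()))
            for a in cluster_aggregates(
                make_cloud(rows[perm], cols[perm], r[perm]), 10.0
            )
        }
        assert sets1 == sets2

    def test_two_spheres_with_depth_gap_split(self, clean_f200):
        scene = Scene(
            [
                SpheroidFruit([-30.0, 0.0, 350.0], 50.0, 50.0),
                SpheroidFruit([30.0, 0.0, 500.0], 50.0, 50.0),
            ],
            clean_f200,
        )
        frame, _ = render_depth(scene, 0)
        cloud = frame_to_points(frame, clean_f200)
        assert len(cluster_aggregates(cloud, 10.0)) == 2


class TestBranchFilter:
    def test_thin_long_strip_is_removed(self):
        rows, cols = np.nonzero(np.ones((3, 200)))
        cloud = make_cloud(rows, cols, np.full(rows.size, 300.0))
        aggs = cluster_aggregates(cloud, 10.0)
        kept = filter_branches(aggs, max_minor_px=6.0, min_elong=4.0)
        assert kept == []
        assert aggs[0].kind == "branch"

    def test_disc_is_retained(self):
        yy, xx = np.mgrid[-30:31, -30:31]
        mask = xx * xx + yy * yy <= 30 * 30
        rows, cols = np.nonzero(mask)
        cloud = make_cloud(rows, cols, np.full(rows.size, 300.0))
        aggs = cluster_aggregates(cloud, 10.0)
        assert filter_branches(aggs) == aggs

    def test_moments_agree_with_skimage(self):
        skimage = pytest.importorskip("skimage.measure")
        rng = np.random.default_rng(3)
        img = np.zeros((50, 70), dtype=int)
        img[10:14, 5:65] = 1
        props = skimage.regionprops(img)[0]
        rows, cols = np.nonzero(img)
        lam1, lam2 = footprint_moments(rows, cols)
        assert 4.0 * np.sqrt(lam2) == pytest.approx(props.axis_minor_length, rel=1e-6)
        assert 4.0 * np.sqrt(lam1) == pytest.approx(props.axis_major_length, rel=1e-6)

    def test_empty_input(self):
        assert filter_branches([]) == []


class TestIsolatedAdherentSplit:
    @pytest.mark.parametrize(
        "count,N0,kind",
        [(500, 1000, "isolated"), (5000, 1000, "adherent"), (1000, 1000, "adherent")],
    )
    def test_threshold_rule(self, count, N0, kind):
        rng = np.random.default_rng(1)
        pix = {(int(a), int(b)) for a, b in rng.integers(0, 200, size=(count * 2, 2))}
        pix = sorted(pix)[:count]
        rows = np.array([p[0] for p in pix])
        cols = np.array([p[1] for p in pix])
        cloud = make_cloud(rows, cols, np.full(count, 300.0))
        from spherecut import Aggregate

        agg = Aggregate(cloud, np.arange(count), id=0)
        split_isolated_adherent([agg], N0)
        assert agg.kind == kind

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            split_isolated_adherent([], 0)
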