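import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from smlmclust import (
    ClusterScenario,
    LocalizationTable,
    build_cluster_shape,
    generate_cell_shape,
    segment,
    simulate_field,
    summarize,
)
from smlmclust.segment import build_all_shapes


def _table(coords):
    return LocalizationTable(np.asarray(coords, dtype=float))


class TestSegment:
    def test_walk_and_stop_hand_trace(self):
        # A(0) B(10) C(20) clustered, D(500) not, E(600) clustered
        table = _table([[0, 0], [10, 0], [20, 0], [500, 0], [600, 0]])
        labels = np.array([1, 1, 1, 0, 1])
        out = segment(table, labels, min_cluster_size=2)
        # {A,B,C} survives; E is a singleton (its nearest neighbor D is
        # non-clustered, stopping the walk immediately) and is demoted
        assert out.n_clusters == 1
        np.testing.assert_array_equal(sorted(out.clusters[1]), [0, 1, 2])
        assert out.cluster_id[4] == 0
        out_all = segment(table, labels, min_cluster_size=1)
        assert out_all.n_clusters == 2
        np.testing.assert_array_equal(out_all.clusters[2], [4])

    def test_all_nonclustered_yields_no_clusters(self):
        table = _table(np.random.default_rng(0).uniform(0, 100, (20, 2)))
        out = segment(table, np.zeros(20, int))
        assert out.n_clusters == 0
        assert np.all(out.cluster_id == 0)

    def test_two_separated_clusters_recovered_exactly(self):
        # two tight clusters far apart, with sparse background between:
        # the walk stops at the first background point, never jumping the gap
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 50, (15, 2))
        b = rng.uniform(0, 50, (15, 2)) + [5000.0, 0.0]
        bg = np.column_stack([rng.uniform(-500, 5500, 10), rng.uniform(-500, 550, 10)])
        table = _table(np.vstack([a, b, bg]))
        labels = np.r_[np.ones(30, int), np.zeros(10, int)]
        out = segment(table, labels, min_cluster_size=3)
        assert out.n_clusters == 2
        truth = np.r_[np.zeros(15, int), np.ones(15, int)]
        assert adjusted_rand_score(truth, out.cluster_id[:30]) == 1.0

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        table = _table(rng.uniform(0, 2000, (200, 2)))
        labels = rng.integers(0, 2, 200)
        out = segment(table, labels, min_cluster_size=2)
        seen = np.zeros(200, bool)
        for cid, members in out.clusters.items():
            assert not seen[members].any()  # disjoint
            seen[members] = True
            assert np.all(labels[members] >= 1)
            assert np.all(out.cluster_id[members] == cid)
            assert len(members) >= 2
        assert np.all(out.cluster_id[~seen] == 0)

    def test_ground_truth_label_recovery_on_viable_scenarios(self):
        """Perfect labels + well-separated clusters -> exact membership (ARI 1)."""
        cell = generate_cell_shape(seed=21, mean_diameter_um=2.3)
        scenario = ClusterScenario(100, 20, 20, 30)  # 1 cluster/µm², r=30nm
        hits = 0
        n_fields = 10
        for rep in range(n_fields):
            table, truth = simulate_field(scenario, cell, seed=100 + rep)
            # require inter-seed separation > 4x radius for the guarantee
            from scipy.spatial.distance import pdist

            if pdist(truth.seed_positions).min() <= 4 * 30:
                n_fields -= 1
                continue
            out = segment(table, (truth.label >= 1).astype(int), min_cluster_size=3)
            # the final, under-filled true cluster may fall below the
            # reporting floor; count true clusters of reportable size
            true_sizes = np.bincount(truth.true_cluster_id)[1:]
            if (
                out.n_clusters == (true_sizes >= 3).sum()
                and adjusted_rand_score(
                    truth.true_cluster_id[truth.label >= 1],
                    out.cluster_id[truth.label >= 1],
                )
                == 1.0
            ):
                hits += 1
        assert n_fields > 0 and hits / n_fields >= 0.95

    def test_misaligned_labels_error(self):
        table = _table([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="align"):
            segment(table, np.array([1]))


def rasterized_shape_area(points, disc_r, erosion, res=0.05):
    """Pixel-counting oracle for the disc-union-then-erode construction.

    Union membership is exact at pixel centres (nearest-member distance
    <= disc radius); erosion keeps pixels whose distance to the union's
    complement exceeds the erosion radius.  The half-pixel bias of the
    distance transform is O(perimeter x res), negligible at 0.05 nm.
    """
    from scipy.ndimage import distance_transform_edt
    from scipy.spatial import cKDTree

    points = np.asarray(points, float)
    pad = disc_r + 4 * res
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    xs = np.arange(lo[0], hi[0], res)
    ys = np.arange(lo[1], hi[1], res)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    d, _ = cKDTree(points).query(grid, k=1, workers=-1)
    union = (d <= disc_r).reshape(len(xs), len(ys))
    if erosion > 0:
        eroded = distance_transform_edt(union) * res > erosion
    else:
        eroded = union
    return eroded.sum() * res**2


class TestClusterShape:
    def test_two_point_disc_union_closed_form(self):
        d = 30.0
        shape = build_cluster_shape(
            np.array([[0.0, 0.0], [d, 0.0]]), disc_factor=1.0, erosion_factor=0.0
        )
        assert shape.mean_nnd_nm == pytest.approx(d)
        # two discs of radius d at distance d: 2πd² minus one lens
        lens = 2 * d**2 * np.arccos(0.5) - (d / 2) * np.sqrt(3) * d
        expected = 2 * np.pi * d**2 - lens
        assert shape.area_nm2 == pytest.approx(expected, rel=1e-3)

    def test_singleton_disc_minus_erosion(self):
        shape = build_cluster_shape(
            np.array([[5.0, 7.0]]), disc_factor=1.0, erosion_factor=0.5,
            singleton_radius_nm=20.0,
        )
        # disc radius 20 eroded by 10 -> disc of radius 10
        assert shape.area_nm2 == pytest.approx(np.pi * 100.0, rel=1e-3)

    def test_random_cluster_matches_rasterization_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 60, (20, 2))
        shape = build_cluster_shape(pts, disc_factor=1.0, erosion_factor=0.5)
        r = shape.mean_nnd_nm
        oracle = rasterized_shape_area(pts, r, 0.5 * r)
        assert shape.area_nm2 == pytest.approx(oracle, rel=0.02)

    def test_members_inside_uneroded_outline(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 50, (15, 2))
        shape = build_cluster_shape(pts, disc_factor=1.0, erosion_factor=0.0)
        from shapely.geometry import Point, Polygon
        from shapely.ops import unary_union

        outline = unary_union([Polygon(p) for p in shape.polygons]).buffer(1e-9)
        assert all(outline.contains(Point(p)) for p in pts)

    def test_erosion_monotonicity(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 80, (25, 2))
        areas = [
            build_cluster_shape(pts, disc_factor=1.0, erosion_factor=e).area_nm2
            for e in (0.0, 0.25, 0.5, 0.75)
        ]
        assert areas == sorted(areas, reverse=True)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 60, (12, 2))
        base = build_cluster_shape(pts).area_nm2
        shifted = build_cluster_shape(pts + [1e6, -5e5]).area_nm2
        assert shifted == pytest.approx(base, rel=1e-6)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = build_cluster_shape(pts @ rot.T).area_nm2
        # rotation exact up to the polygonal disc approximation
        assert rotated == pytest.approx(base, rel=1e-4)

    def test_annihilating_erosion_falls_back_unflagged_area(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0]])
        shape = build_cluster_shape(pts, disc_factor=1.0, erosion_factor=10.0)
        assert not shape.eroded
        assert shape.area_nm2 > 0

    def test_empty_members_error(self):
        with pytest.raises(ValueError):
            build_cluster_shape(np.empty((0, 2)))


class TestSummarize:
    def _assignment_and_shapes(self, seed=7, n_clusters=5, n_noise=50):
        rng = np.random.default_rng(seed)
        pts, labels = [], []
        for i in range(n_clusters):
            centre = rng.uniform(200, 800, 2) + i * 1000
            pts.append(centre + rng.uniform(-20, 20, (10, 2)))
            labels += [1] * 10
        pts.append(rng.uniform(0, 6000, (n_noise, 2)))
        labels += [0] * n_noise
        table = _table(np.vstack(pts))
        out = segment(table, np.array(labels), min_cluster_size=3)
        return table, out

    def test_cluster_density_and_pct(self):
        table, out = self._assignment_and_shapes()
        shapes = build_all_shapes(table, out)
        stats = summarize(out, shapes, analysis_area_um2=1.0)
        assert stats.clusters_per_um2 == out.n_clusters / 1.0
        expected_pct = 100.0 * (out.cluster_id > 0).sum() / table.n
        assert stats.pct_points_clustered == pytest.approx(expected_pct)

    def test_missing_shape_errors(self):
        table, out = self._assignment_and_shapes()
        shapes = build_all_shapes(table, out)
        shapes.pop(next(iter(shapes)))
        with pytest.raises(ValueError, match="missing"):
            summarize(out, shapes, analysis_area_um2=1.0)

    def test_invalid_area_errors(self):
        table, out = self._assignment_and_shapes()
        with pytest.raises(ValueError):
            summarize(out, build_all_shapes(table, out), analysis_area_um2=0.0)
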