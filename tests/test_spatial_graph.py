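"""Grid centroids, MST construction, Delaunay graphs, edge types."""

import numpy as np
import pytest

import habitatgraph as hg
from habitatgraph.errors import DegenerateGeometryError, InsufficientPointsError

from _oracles import brute_force_mst_weight, circumcircle, random_spanning_tree_weight


class TestGridCentroids:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 4] = True
        pts = hg.grid_centroids(mask, (1.0, 1.0), 8)
        np.testing.assert_allclose(pts, [[3.0, 4.0]])

    def test_mean_of_two_pixels_same_cell(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = mask[0, 2] = True
        pts = hg.grid_centroids(mask, (1.0, 1.0), 8)
        np.testing.assert_allclose(pts, [[0.0, 1.0]])

    def test_cell_partition(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = mask[9, 0] = True
        pts = hg.grid_centroids(mask, (1.0, 1.0), 8)
        assert pts.shape == (2, 2)

    def test_empty_mask_empty_points(self):
        assert hg.grid_centroids(np.zeros((5, 5), bool)).shape == (0, 2)

    def test_translation_consistency(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((40, 40), bool)
        mask[4:22, 3:19] = rng.random((18, 16)) < 0.5
        mask[5, 5] = True
        shifted = np.roll(np.roll(mask, 8, axis=0), 16, axis=1)
        p0 = hg.grid_centroids(mask, (1.0, 1.0), 8)
        p1 = hg.grid_centroids(shifted, (1.0, 1.0), 8)
        np.testing.assert_allclose(p1, p0 + [8.0, 16.0])

    def test_anisotropic_spacing(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 3] = True
        np.testing.assert_allclose(
            hg.grid_centroids(mask, (2.0, 0.5), 8), [[4.0, 1.5]]
        )


class TestBuildMST:
    def test_two_points(self):
        tree = hg.build_mst(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert len(tree.edges) == 1
        assert tree.total_weight == pytest.approx(5.0)

    def test_equilateral_triangle(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        tree = hg.build_mst(pts)
        assert tree.total_weight == pytest.approx(2.0)
        assert len(tree.edges) == 2

    def test_single_point_raises(self):
        with pytest.raises(InsufficientPointsError):
            hg.build_mst(np.array([[1.0, 1.0]]))

    def test_tree_structure(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, (20, 2))
        tree = hg.build_mst(pts)
        assert len(tree.edges) == 19
        # connectivity: union-find over the returned edges reaches one root
        parent = list(range(20))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in tree.edges:
            parent[find(int(i))] = find(int(j))
        assert len({find(v) for v in range(20)}) == 1

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            pts = rng.uniform(0, 10, (n, 2))
            assert hg.build_mst(pts).total_weight == pytest.approx(
                brute_force_mst_weight(pts), rel=1e-12
            )

    def test_not_heavier_than_random_trees(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (12, 2))
        mst_w = hg.build_mst(pts).total_weight
        for _ in range(1000):
            assert mst_w <= random_spanning_tree_weight(pts, rng) + 1e-9

    def test_deterministic_under_ties(self):
        # unit square: four equal sides, tie-break must be reproducible
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        e1 = hg.build_mst(pts).edges
        e2 = hg.build_mst(pts).edges
        np.testing.assert_array_equal(e1, e2)
        assert hg.build_mst(pts).total_weight == pytest.approx(3.0)


class TestBuildDelaunay:
    def test_single_triangle(self):
        g = hg.build_delaunay(np.array([[0.0, 0], [1, 0], [0, 1]]), [0, 1, 2])
        assert len(g.edges) == 3

    def test_quadrilateral_has_five_edges_and_empty_circumcircles(self):
        pts = np.array([[0.0, 0], [3, 0], [2, 2], [0, 1]])
        g = hg.build_delaunay(pts, [0, 1, 2, 3])
        assert len(g.edges) == 5
        self._check_empty_circumcircles(g)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            hg.build_delaunay(np.array([[0.0, 0], [1, 0], [2, 0]]), [0, 0, 0])

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateGeometryError):
            hg.build_delaunay(np.array([[0.0, 0], [1, 0]]), [0, 0])

    def test_random_point_sets_satisfy_circumcircle_property(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 51))
            pts = rng.uniform(0, 100, (n, 2))
            g = hg.build_delaunay(pts, rng.integers(0, 4, n))
            self._check_empty_circumcircles(g)

    @staticmethod
    def _check_empty_circumcircles(graph):
        from scipy.spatial import Delaunay

        tri = Delaunay(graph.points)
        for simplex in tri.simplices:
            center, radius = circumcircle(*graph.points[simplex])
            d = np.linalg.norm(graph.points - center, axis=1)
            inside = d < radius - 1e-9
            inside[simplex] = False
            assert not inside.any()

    def test_edge_types_attached(self):
        g = hg.build_delaunay(
            np.array([[0.0, 0], [1, 0], [0, 1]]), [0, 0, 3]
        )
        types = sorted(g.edge_types.tolist())
        assert types == sorted(
            [hg.edge_type(0, 0), hg.edge_type(0, 3), hg.edge_type(0, 3)]
        )


class TestEdgeType:
    def test_first_same_label_pair(self):
        L = hg.HabitatLabel
        assert hg.edge_type(L.T1_HIGH, L.T1_HIGH) == 0

    def test_symmetry(self):
        L = hg.HabitatLabel
        for a in L:
            for b in L:
                assert hg.edge_type(a, b) == hg.edge_type(b, a)

    def test_exactly_ten_types(self):
        L = hg.HabitatLabel
        indices = {hg.edge_type(a, b) for a in L for b in L}
        assert indices == set(range(10))
        assert hg.N_EDGE_TYPES == 10

    def test_documented_enumeration_order(self):
        pairs = hg.edge_type_pairs()
        assert [tuple(map(int, p)) for p in pairs[:4]] == [(0, 0), (1, 1), (2, 2), (3, 3)]
        assert [tuple(map(int, p)) for p in pairs[4:]] == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
        ]
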