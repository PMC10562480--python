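"""Graph run-length matrix accumulation and its 24 features."""

import numpy as np
import pytest

import habitatgraph as hg
from habitatgraph.errors import DegenerateGeometryError, EmptyMatrixError
from habitatgraph.grlm import GraphRunLengthMatrix

from conftest import random_labeled_graph
from _oracles import grlm_oracle


def make_graph(points, labels, edges):
    points = np.asarray(points, float)
    labels = np.asarray(labels, int)
    edges = np.asarray(edges, int)
    types = np.array([hg.edge_type(labels[i], labels[j]) for i, j in edges])
    return hg.TriangulatedGraph(points=points, labels=labels, edges=edges, edge_types=types)


class TestComputeGRLM:
    def test_single_edge_counts_both_endpoints(self):
        g = make_graph([[0, 0], [1, 0]], [0, 0], [[0, 1]])
        M = hg.compute_grlm(g)
        assert M.counts[hg.edge_type(0, 0), 0] == 2
        assert M.n_runs == 2

    def test_two_edge_path_unbounded_window(self):
        g = make_graph([[0, 0], [1, 0], [2, 0]], [0, 0, 0], [[0, 1], [1, 2]])
        M = hg.compute_grlm(g)
        t = hg.edge_type(0, 0)
        assert M.counts[t, 1] == 2  # from both ends
        assert M.counts[t, 0] == 1  # from the middle
        assert M.n_runs == 3

    def test_window_truncates_runs(self):
        g = make_graph([[0, 0], [1, 0], [2, 0]], [0, 0, 0], [[0, 1], [1, 2]])
        M = hg.compute_grlm(g, window_radius_mm=1.5)
        t = hg.edge_type(0, 0)
        assert M.counts[t, 0] == 3  # all runs cut to length 1
        assert M.counts[t, 1:].sum() == 0

    def test_l_max_caps_run_length(self):
        pts = [[i, 0.0] for i in range(6)]
        g = make_graph(pts, [0] * 6, [[i, i + 1] for i in range(5)])
        M = hg.compute_grlm(g, l_max=3)
        assert M.counts[hg.edge_type(0, 0)].sum() == 6
        assert M.counts[hg.edge_type(0, 0), 2] >= 2  # end nodes capped at 3

    def test_run_conservation(self):
        # n_r equals the number of (node, incident edge type) pairs,
        # regardless of the window radius
        rng = np.random.default_rng(0)
        for radius in (None, 5.0, 0.5):
            g = random_labeled_graph(rng, 10)
            pairs = set()
            for (i, j), t in zip(g.edges, g.edge_types):
                pairs.add((int(i), int(t)))
                pairs.add((int(j), int(t)))
            assert hg.compute_grlm(g, window_radius_mm=radius).n_runs == len(pairs)

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(1)
        for k in range(15):
            n = int(rng.integers(4, 13))
            g = random_labeled_graph(rng, n)
            radius = None if k % 3 == 0 else float(rng.uniform(2, 15))
            M = hg.compute_grlm(g, window_radius_mm=radius, l_max=10)
            expected = grlm_oracle(g.points, g.edges, g.edge_types, radius, 10)
            np.testing.assert_array_equal(M.counts, expected)

    def test_shrinking_window_monotonically_reduces_lpe(self):
        rng = np.random.default_rng(2)
        g = random_labeled_graph(rng, 12)
        radii = [None, 20.0, 10.0, 5.0, 2.0, 0.5, 1e-9]
        lpes = [
            hg.grlm_features(hg.compute_grlm(g, window_radius_mm=r))["lpe"]
            for r in radii
        ]
        assert all(a >= b - 1e-12 for a, b in zip(lpes, lpes[1:]))
        assert lpes[-1] == pytest.approx(1.0)


class TestGRLMFeatures:
    @staticmethod
    def matrix(counts, l_max=10):
        G = np.zeros((10, l_max), dtype=int)
        for (t, l), v in counts.items():
            G[t, l - 1] = v
        return GraphRunLengthMatrix(counts=G, window_radius_mm=None, l_max=l_max)

    def test_single_unit_run(self):
        f = hg.grlm_features(self.matrix({(0, 1): 1}))
        assert (f["spe"], f["lpe"], f["etn"], f["pln"]) == (1.0, 1.0, 1.0, 1.0)

    def test_single_length_two_run(self):
        f = hg.grlm_features(self.matrix({(0, 2): 1}))
        assert f["spe"] == pytest.approx(0.25)
        assert f["lpe"] == pytest.approx(4.0)
        assert f["etn"] == pytest.approx(1.0)
        assert f["pln"] == pytest.approx(1.0)

    def test_hand_computed_path_example(self):
        # G(t,1)=1, G(t,2)=2 (the two-edge path): n_r = 3
        f = hg.grlm_features(self.matrix({(0, 1): 1, (0, 2): 2}))
        assert f["spe"] == pytest.approx(0.5, abs=1e-12)
        assert f["lpe"] == pytest.approx(3.0, abs=1e-12)
        assert f["etn"] == pytest.approx(3.0, abs=1e-12)
        assert f["pln"] == pytest.approx(5.0 / 3.0, abs=1e-12)
        assert f["spe_t0"] == pytest.approx(0.5, abs=1e-12)
        assert f["lpe_t0"] == pytest.approx(3.0, abs=1e-12)

    def test_empty_matrix_raises(self):
        with pytest.raises(EmptyMatrixError):
            hg.grlm_features(self.matrix({}))

    def test_absent_types_are_missing(self):
        f = hg.grlm_features(self.matrix({(3, 1): 4}))
        assert np.isfinite(f["spe_t3"]) and np.isfinite(f["lpe_t3"])
        for t in set(range(10)) - {3}:
            assert np.isnan(f[f"spe_t{t}"]) and np.isnan(f[f"lpe_t{t}"])

    def test_spe_le_one_le_lpe(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            G = rng.integers(0, 5, size=(10, 6))
            if G.sum() == 0:
                continue
            M = GraphRunLengthMatrix(counts=G, window_radius_mm=None, l_max=6)
            f = hg.grlm_features(M)
            assert f["spe"] <= 1.0 + 1e-12 <= f["lpe"] + 2e-12
        # equality iff all runs have length 1
        f = hg.grlm_features(self.matrix({(0, 1): 3, (5, 1): 2}))
        assert f["spe"] == pytest.approx(1.0) and f["lpe"] == pytest.approx(1.0)

    def test_relabeling_permutes_per_type_features(self):
        rng = np.random.default_rng(4)
        g = random_labeled_graph(rng, 12)
        perm = {0: 2, 1: 3, 2: 0, 3: 1}
        labels2 = np.array([perm[int(l)] for l in g.labels])
        g2 = make_graph(g.points, labels2, g.edges)
        f1 = hg.grlm_features(hg.compute_grlm(g))
        f2 = hg.grlm_features(hg.compute_grlm(g2))
        for name in ("spe", "lpe", "etn", "pln"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-12)
        pairs = hg.edge_type_pairs()
        for t, (a, b) in enumerate(pairs):
            t2 = hg.edge_type(perm[int(a)], perm[int(b)])
            np.testing.assert_allclose(
                f2[f"spe_t{t2}"], f1[f"spe_t{t}"], rtol=1e-12, equal_nan=True
            )


class TestSubjectGRLMFeatures:
    def test_exactly_24_named_features(self, phantom_masks):
        f = hg.subject_grlm_features(phantom_masks)
        assert list(f) == hg.GRLM_FEATURE_NAMES
        assert len(f) == 24

    def test_absent_habitat_blanks_its_edge_types(self, phantom_masks):
        empty = np.zeros_like(phantom_masks[hg.HabitatLabel.T1_HIGH])
        masks = hg.HabitatMasks(
            masks={**phantom_masks.masks, hg.HabitatLabel.T1_HIGH: empty},
            gmm_threshold_t1=phantom_masks.gmm_threshold_t1,
            gmm_threshold_t2=phantom_masks.gmm_threshold_t2,
            gmm_means=phantom_masks.gmm_means,
            spacing_mm=phantom_masks.spacing_mm,
        )
        f = hg.subject_grlm_features(masks)
        involving = [
            t for t, (a, b) in enumerate(hg.edge_type_pairs())
            if hg.HabitatLabel.T1_HIGH in (a, b)
        ]
        for t in involving:
            assert np.isnan(f[f"spe_t{t}"]) and np.isnan(f[f"lpe_t{t}"])

    def test_degenerate_geometry_raises(self, phantom_masks):
        tiny = {label: np.zeros_like(phantom_masks[label]) for label in hg.HabitatLabel}
        tiny[hg.HabitatLabel.T1_LOW][0, 0] = True
        tiny[hg.HabitatLabel.T1_LOW][0, 9] = True
        masks = hg.HabitatMasks(
            masks=tiny,
            gmm_threshold_t1=0.5,
            gmm_threshold_t2=0.5,
            gmm_means={},
            spacing_mm=(1.0, 1.0),
        )
        with pytest.raises(DegenerateGeometryError):
            hg.subject_grlm_features(masks)
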