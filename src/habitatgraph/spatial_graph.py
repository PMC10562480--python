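"""Spatial graph constructions over habitat centroid maps.

A square grid (default 8 px, i.e. 8 mm at 1 mm spacing) is overlaid on each
habitat mask's bounding box; each grid cell containing habitat pixels emits the
centre of mass of those pixels, in millimetres. Per-habitat centroids are
joined by a Euclidean minimum spanning tree; the combined centroids of all four
habitats are Delaunay-triangulated into a labeled graph whose edges carry one
of 10 edge types (unordered habitat-label pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateGeometryError, InsufficientPointsError
from .habitats import HabitatLabel, HabitatMasks

__all__ = [
    "CentroidMap",
    "SpanningTree",
    "TriangulatedGraph",
    "grid_centroids",
    "centroid_map",
    "build_mst",
    "build_delaunay",
    "edge_type",
    "edge_type_pairs",
    "N_EDGE_TYPES",
]

# Edge-type enumeration: 4 same-label types first, in habitat-label order,
# then the 6 mixed pairs in lexicographic label order.
_EDGE_TYPE_PAIRS: list[tuple[int, int]] = [(a, a) for a in range(4)] + [
    (a, b) for a in range(4) for b in range(a + 1, 4)
]
_PAIR_TO_INDEX = {pair: i for i, pair in enumerate(_EDGE_TYPE_PAIRS)}
N_EDGE_TYPES = len(_EDGE_TYPE_PAIRS)


def edge_type(a: HabitatLabel, b: HabitatLabel) -> int:
    """Stable index (0-9) of the unordered habitat-label pair {a, b}."""
    a, b = int(a), int(b)
    return _PAIR_TO_INDEX[(a, b) if a <= b else (b, a)]


def edge_type_pairs() -> list[tuple[HabitatLabel, HabitatLabel]]:
    """The 10 edge types in enumeration order."""
    return [(HabitatLabel(a), HabitatLabel(b)) for a, b in _EDGE_TYPE_PAIRS]


@dataclass
class CentroidMap:
    """Habitat-labeled centroid points in mm coordinates."""

    points: np.ndarray  # (n, 2) float, mm
    labels: np.ndarray  # (n,) int habitat labels
    grid_spacing_px: int

    @property
    def per_habitat_counts(self) -> dict:
        return {
            label: int(np.sum(self.labels == int(label))) for label in HabitatLabel
        }


@dataclass
class SpanningTree:
    """Euclidean minimum spanning tree over a habitat's centroids."""

    points: np.ndarray  # (n, 2) mm
    edges: np.ndarray  # (n-1, 2) int vertex indices
    weights: np.ndarray  # (n-1,) edge lengths in mm
    habitat: HabitatLabel | None = None

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class TriangulatedGraph:
    """Delaunay graph over labeled points; each edge carries an edge type."""

    points: np.ndarray  # (n, 2) mm
    labels: np.ndarray  # (n,) int habitat labels
    edges: np.ndarray  # (m, 2) int, each row sorted, rows unique
    edge_types: np.ndarray  # (m,) int in 0..9


def grid_centroids(
    mask: np.ndarray,
    spacing_mm: tuple[float, float] = (1.0, 1.0),
    grid_spacing: int = 8,
) -> np.ndarray:
    """Per-grid-cell centres of mass of a binary mask, in mm.

    The grid is anchored at the top-left corner of the mask's bounding box and
    partitions it into ``grid_spacing`` x ``grid_spacing`` pixel cells. Every
    cell containing at least one mask pixel emits one point: the mean pixel
    coordinate of its mask pixels, multiplied by the pixel spacing. Cells are
    emitted in (cell-row, cell-col) order. An empty mask yields an empty array.
    """
    mask = np.asarray(mask, dtype=bool)
    if grid_spacing < 1:
        raise ValueError("grid_spacing must be >= 1")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.empty((0, 2), dtype=float)
    r0, c0 = rows.min(), cols.min()
    cell_r = (rows - r0) // grid_spacing
    cell_c = (cols - c0) // grid_spacing
    cell_id = cell_r * (cell_c.max() + 1) + cell_c
    order = np.argsort(cell_id, kind="stable")
    cell_id, rows, cols = cell_id[order], rows[order], cols[order]
    uniq, start = np.unique(cell_id, return_index=True)
    sr, sc = spacing_mm
    points = np.empty((uniq.size, 2), dtype=float)
    bounds = np.append(start, cell_id.size)
    for k in range(uniq.size):
        sel = slice(bounds[k], bounds[k + 1])
        points[k, 0] = rows[sel].mean() * sr
        points[k, 1] = cols[sel].mean() * sc
    return points


def centroid_map(masks: HabitatMasks, grid_spacing: int = 8) -> CentroidMap:
    """Combined centroid map over all four habitats."""
    pts, labs = [], []
    for label in HabitatLabel:
        p = grid_centroids(masks[label], masks.spacing_mm, grid_spacing)
        pts.append(p)
        labs.append(np.full(len(p), int(label), dtype=int))
    return CentroidMap(
        points=np.vstack(pts) if pts else np.empty((0, 2)),
        labels=np.concatenate(labs) if labs else np.empty(0, dtype=int),
        grid_spacing_px=grid_spacing,
    )


def build_mst(points: np.ndarray, habitat: HabitatLabel | None = None) -> SpanningTree:
    """Minimum spanning tree of the complete Euclidean graph on ``points``.

    Kruskal's algorithm with edges sorted by (weight, i, j): ties between
    equal-weight edges are broken by lexicographic vertex-index order, so a
    fixed point set always yields the same edge set.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise InsufficientPointsError(f"MST needs >= 2 points, got {n}")
    dists = squareform(pdist(points))
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, dists[iu, ju]))
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = np.empty((n - 1, 2), dtype=int)
    weights = np.empty(n - 1, dtype=float)
    k = 0
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges[k] = (i, j)
            weights[k] = dists[i, j]
            k += 1
            if k == n - 1:
                break
    return SpanningTree(points=points, edges=edges, weights=weights, habitat=habitat)


def build_delaunay(points: np.ndarray, labels: np.ndarray) -> TriangulatedGraph:
    """Delaunay triangulation of labeled points, as an edge-typed graph.

    Labels are ignored by the geometry and attached to vertices; each edge is
    assigned the edge type of its endpoint labels.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or all points collinear.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(points) != len(labels):
        raise ValueError("points and labels length mismatch")
    if len(points) < 3:
        raise DegenerateGeometryError(
            f"triangulation needs >= 3 points, got {len(points)}"
        )
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise DegenerateGeometryError(f"no valid triangulation: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("degenerate (collinear) point set")
    pair_set = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            pair_set.add((i, j) if i < j else (j, i))
    edges = np.array(sorted(pair_set), dtype=int)
    types = np.array(
        [edge_type(labels[i], labels[j]) for i, j in edges], dtype=int
    )
    return TriangulatedGraph(points=points, labels=labels, edges=edges, edge_types=types)
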