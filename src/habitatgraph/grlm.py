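"""Graph run-length matrices over the all-habitat Delaunay graph.

The graph run-length matrix G(t, l) counts, over all initial nodes, runs of
l consecutive edges of type t: for every node v and every edge type t with at
least one type-t edge incident to v, the run length is the largest number of
consecutive type-t edges along any simple path starting at v, and G(t, run
length) is incremented by one. A node therefore contributes at most one run per
edge type, and the total number of runs n_r equals the number of
(node, incident edge type) pairs.

An optional circular window of radius R (mm) centred on the initial node
truncates runs: the first edge of a run always counts, but a path may only be
extended to nodes lying strictly within R of the initial node. With R -> 0 all
runs collapse to length 1; with an unbounded window (the default) runs are
limited only by the simple-path structure and the path-length cap ``l_max``.

From G, 24 features are computed: four global (short/long path emphasis SPE
and LPE, edge-type nonuniformity ETN, path-length nonuniformity PLN) and, for
each of the 10 edge types t, SPE(t) and LPE(t) normalized by that type's run
count n_r(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMatrixError
from .habitats import HabitatMasks
from .spatial_graph import (
    N_EDGE_TYPES,
    TriangulatedGraph,
    build_delaunay,
    centroid_map,
)

__all__ = [
    "GraphRunLengthMatrix",
    "GRLM_FEATURE_NAMES",
    "compute_grlm",
    "grlm_features",
    "subject_grlm_features",
]

GRLM_FEATURE_NAMES = (
    ["spe", "lpe", "etn", "pln"]
    + [f"spe_t{t}" for t in range(N_EDGE_TYPES)]
    + [f"lpe_t{t}" for t in range(N_EDGE_TYPES)]
)


@dataclass
class GraphRunLengthMatrix:
    """Run counts G(t, l) for edge types t (0-9) and path lengths l (1..l_max)."""

    counts: np.ndarray  # (N_EDGE_TYPES, l_max) int
    window_radius_mm: float | None
    l_max: int

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def per_type_runs(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def per_length_runs(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _longest_run(
    start: int,
    adj: dict,
    points: np.ndarray,
    radius: float | None,
    l_max: int,
) -> int:
    """Longest same-type simple path from ``start`` under the window rule.

    The first edge is always admissible; every later node must lie strictly
    within ``radius`` of the start node. Depth-first search capped at l_max.
    """
    if radius is None:
        in_window = None
    else:
        d = np.linalg.norm(points - points[start], axis=1)
        in_window = d < radius
    best = 1

    def extend(node: int, depth: int, visited: set) -> None:
        nonlocal best
        if depth > best:
            best = depth
        if depth >= l_max:
            return
        for nxt in adj[node]:
            if nxt in visited:
                continue
            if in_window is not None and not in_window[nxt]:
                continue
            visited.add(nxt)
            extend(nxt, depth + 1, visited)
            visited.remove(nxt)

    for first in adj[start]:
        extend(first, 1, {start, first})
    return best


def compute_grlm(
    graph: TriangulatedGraph,
    window_radius_mm: float | None = None,
    l_max: int = 10,
) -> GraphRunLengthMatrix:
    """Accumulate the run-length matrix over every node of the graph.

    For each node and each edge type with an incident edge of that type, one
    run of the node's maximal consecutive same-type path length (capped at
    ``l_max``, truncated by the window) is recorded. Isolated nodes and
    (node, type) pairs without incident edges contribute nothing.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    counts = np.zeros((N_EDGE_TYPES, l_max), dtype=np.int64)
    # per-type adjacency restricted to nodes with incident type-t edges
    adj_by_type: list[dict] = [dict() for _ in range(N_EDGE_TYPES)]
    for (i, j), t in zip(graph.edges, graph.edge_types):
        adj_by_type[t].setdefault(int(i), []).append(int(j))
        adj_by_type[t].setdefault(int(j), []).append(int(i))
    for t, adj in enumerate(adj_by_type):
        for v in adj:
            length = _longest_run(v, adj, graph.points, window_radius_mm, l_max)
            counts[t, length - 1] += 1
    return GraphRunLengthMatrix(
        counts=counts, window_radius_mm=window_radius_mm, l_max=l_max
    )


def grlm_features(matrix: GraphRunLengthMatrix) -> dict:
    """The 24 named run-length features of a GRLM.

    Global features divide by the total run count n_r; per-type SPE(t)/LPE(t)
    restrict the sums to edge type t and divide by n_r(t). Types with no runs
    have NaN (missing) per-type features.

    Raises
    ------
    EmptyMatrixError
        If the matrix contains no runs.
    """
    G = matrix.counts.astype(float)
    n_r = G.sum()
    if n_r == 0:
        raise EmptyMatrixError("run-length matrix has no runs")
    lengths = np.arange(1, matrix.l_max + 1, dtype=float)
    inv_l2 = 1.0 / lengths**2
    l2 = lengths**2
    per_type = G.sum(axis=1)
    per_length = G.sum(axis=0)
    features: dict = {
        "spe": float((G * inv_l2).sum() / n_r),
        "lpe": float((G * l2).sum() / n_r),
        "etn": float((per_type**2).sum() / n_r),
        "pln": float((per_length**2).sum() / n_r),
    }
    for t in range(N_EDGE_TYPES):
        n_t = per_type[t]
        features[f"spe_t{t}"] = float((G[t] * inv_l2).sum() / n_t) if n_t else np.nan
    for t in range(N_EDGE_TYPES):
        n_t = per_type[t]
        features[f"lpe_t{t}"] = float((G[t] * l2).sum() / n_t) if n_t else np.nan
    return features


def subject_grlm_features(
    masks: HabitatMasks,
    grid_spacing: int = 8,
    window_radius_mm: float | None = None,
    l_max: int = 10,
) -> dict:
    """24 named GRLM features for one subject.

    Centroids from all four habitats are combined into one labeled point set,
    Delaunay-triangulated, and the run-length matrix accumulated over the
    resulting edge-typed graph. Edge types absent from the graph (for example
    every type involving an empty habitat) yield NaN per-type features.
    A degenerate combined point set (< 3 points or collinear) raises
    DegenerateGeometryError.
    """
    cmap = centroid_map(masks, grid_spacing)
    graph = build_delaunay(cmap.points, cmap.labels)
    matrix = compute_grlm(graph, window_radius_mm=window_radius_mm, l_max=l_max)
    return grlm_features(matrix)
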