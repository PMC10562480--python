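"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: spanning trees are
enumerated exhaustively, GRLM runs come from a full simple-path enumeration,
and AUC is the pairwise Mann-Whitney statistic.
"""

from collections import defaultdict
from itertools import combinations

import numpy as np


def brute_force_mst_weight(points: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive enumeration over all
    (n-1)-edge subsets of the complete graph, keeping the spanning ones."""
    n = len(points)
    all_edges = list(combinations(range(n), 2))
    weights = {e: float(np.linalg.norm(points[e[0]] - points[e[1]])) for e in all_edges}
    best = np.inf
    for subset in combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        spanning = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                spanning = False  # cycle => cannot span with n-1 edges
                break
            parent[ri] = rj
        if spanning:
            best = min(best, sum(weights[e] for e in subset))
    return best


def random_spanning_tree_weight(points: np.ndarray, rng: np.random.Generator) -> float:
    """Weight of a random spanning tree (random edge order Kruskal)."""
    n = len(points)
    edges = list(combinations(range(n), 2))
    rng.shuffle(edges)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total = 0.0
    count = 0
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += float(np.linalg.norm(points[i] - points[j]))
            count += 1
            if count == n - 1:
                break
    return total


def grlm_oracle(points, edges, edge_types, radius, l_max, n_types=10) -> np.ndarray:
    """Exhaustive GRLM: enumerate every simple same-type path from every node,
    compute its window-truncated length afterwards, and take the per
    (node, type) maximum. The first edge of a path always counts; the path is
    cut at the first node (beyond the first neighbor) at distance >= radius
    from the start node."""
    points = np.asarray(points, float)
    adj = [defaultdict(list) for _ in range(n_types)]
    for (i, j), t in zip(edges, edge_types):
        adj[t][int(i)].append(int(j))
        adj[t][int(j)].append(int(i))
    counts = np.zeros((n_types, l_max), dtype=int)

    def all_paths(t, path):
        yield path
        for nxt in adj[t][path[-1]]:
            if nxt not in path:
                yield from all_paths(t, path + [nxt])

    for t in range(n_types):
        for v in adj[t]:
            best = 0
            for path in all_paths(t, [v]):
                if len(path) < 2:
                    continue
                length = 1  # first edge always admissible
                for node in path[2:]:
                    if radius is not None and np.linalg.norm(
                        points[node] - points[v]
                    ) >= radius:
                        break
                    length += 1
                best = max(best, min(length, l_max))
            if best > 0:
                counts[t, best - 1] += 1
    return counts


def mann_whitney_auc(probs, labels) -> float:
    """AUC as the pairwise Mann-Whitney statistic (ties count 1/2)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def circumcircle(a, b, c):
    """Center and radius of the circle through three points."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - np.asarray(a, float)))
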