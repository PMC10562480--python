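import numpy as np
import pytest

import habitatgraph as hg


@pytest.fixture(scope="session")
def phantom():
    """One default phantom with well-separated mixture components."""
    return hg.generate_phantom(hg.PhantomParams(seed=42), subject_id="fixture")


@pytest.fixture(scope="session")
def phantom_masks(phantom):
    return hg.make_habitat_masks(phantom, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny balanced cohort with a strong planted clustering effect."""
    spec = hg.CohortSpec(n_per_class=6, clustering_effect=0.8, seed=7)
    return hg.generate_cohort(spec)


def random_labeled_graph(rng, n_nodes, edge_prob=0.35):
    """Random labeled graph for GRLM oracle tests (not necessarily planar)."""
    points = rng.uniform(0, 20, size=(n_nodes, 2))
    labels = rng.integers(0, 4, size=n_nodes)
    edges, types = [], []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((i, j))
                types.append(hg.edge_type(labels[i], labels[j]))
    if not edges:
        edges, types = [(0, 1)], [hg.edge_type(labels[0], labels[1])]
    return hg.TriangulatedGraph(
        points=points,
        labels=np.asarray(labels),
        edges=np.asarray(edges),
        edge_types=np.asarray(types),
    )
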