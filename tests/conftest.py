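"""Shared fixtures: stores loaded with the bundled reconstructions."""

from __future__ import annotations

import random

import pytest

from modelgraph import PropertyGraph
from modelgraph.corpus import import_corpus, link_all
from modelgraph.synthetic import paper_fixtures


@pytest.fixture(scope="session")
def fixture_files() -> dict[str, str]:
    return paper_fixtures()


@pytest.fixture(scope="session")
def fixture_store(fixture_files) -> PropertyGraph:
    """All reconstructed fixtures imported and fully linked."""
    store = PropertyGraph()
    import_corpus(store, fixture_files)
    link_all(store)
    return store


def random_property_graph(
    seed: int,
    n_nodes: int,
    n_edges: int,
    labels=("A", "B", "C"),
    edge_types=("x", "y"),
    acyclic: bool = False,
) -> PropertyGraph:
    """Small random store for oracle-based equivalence tests."""
    rng = random.Random(seed)
    store = PropertyGraph()
    ids = [
        store.add_node({rng.choice(labels)}, {"V": rng.randint(0, 3)})
        for _ in range(n_nodes)
    ]
    for _ in range(n_edges):
        a, b = rng.sample(ids, 2)
        if acyclic and a > b:
            a, b = b, a
        store.add_edge(a, b, rng.choice(edge_types))
    return store
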