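"""Property-graph store: indices, traversal, validation, persistence."""

import random

import pytest

from modelgraph import IntegrityError, PropertyGraph, ValidationError
from modelgraph import graph as g

from conftest import random_property_graph


class TestNodesAndIndices:
    def test_added_node_retrievable_via_every_label(self):
        store = PropertyGraph()
        nid = store.add_node({g.SBML_SPECIES, "EXTRA"}, {"ID": "pM"})
        assert nid in store.nodes_by_label(g.SBML_SPECIES)
        assert nid in store.nodes_by_label("EXTRA")
        assert store.get(nid, "ID") == "pM"

    def test_resource_node_visible_under_resource_label(self):
        store = PropertyGraph()
        nid = store.add_node({g.RESOURCE}, {"URI": "urn:miriam:obo.go:GO%3A0005892"})
        assert store.nodes_by_label(g.RESOURCE) == {nid}

    def test_empty_label_set_rejected(self):
        store = PropertyGraph()
        with pytest.raises(ValidationError):
            store.add_node(set(), {})

    def test_hundred_distinct_labels_resolve_individually(self):
        store = PropertyGraph()
        ids = [store.add_node({f"L{i}"}, {}) for i in range(100)]
        assert len(set(ids)) == 100
        for i, nid in enumerate(ids):
            assert store.nodes_by_label(f"L{i}") == {nid}

    def test_label_index_matches_bruteforce_scan(self):
        store = random_property_graph(seed=7, n_nodes=40, n_edges=60)
        for label in ("A", "B", "C"):
            scan = {n for n in store.node_ids() if label in store.labels(n)}
            assert store.nodes_by_label(label) == scan

    def test_attribute_index_follows_updates(self):
        store = PropertyGraph()
        nid = store.add_node({"X"}, {"K": "old"})
        store.set_attribute(nid, "K", "new")
        assert store.nodes_by_attribute("X", "K", "new") == {nid}
        assert store.nodes_by_attribute("X", "K", "old") == set()

    def test_unknown_label_yields_empty_set(self):
        assert PropertyGraph().nodes_by_label("NOPE") == set()


class TestEdges:
    def test_edge_traversable_in_both_directions(self):
        store = PropertyGraph()
        pm = store.add_node({g.SBML_SPECIES}, {"ID": "pM"})
        cell = store.add_node({g.SBML_COMPARTMENT}, {"ID": "Cell"})
        store.add_edge(pm, cell, g.IS_CONTAINED_IN)
        assert store.neighbors(cell, g.IS_CONTAINED_IN, "in") == {pm}
        assert store.neighbors(pm, g.IS_CONTAINED_IN, "out") == {cell}

    def test_unknown_endpoint_rejected(self):
        store = PropertyGraph()
        nid = store.add_node({"X"}, {})
        with pytest.raises(IntegrityError):
            store.add_edge(nid, nid + 99, "t")

    def test_self_edge_allowed_but_flagged(self):
        store = PropertyGraph()
        nid = store.add_node({g.DOCUMENT}, {})
        store.add_edge(nid, nid, g.IS_A)
        report = store.validate()
        assert (nid, g.IS_A) in report.self_edges

    def test_parallel_edges_of_different_types_coexist(self):
        store = PropertyGraph()
        a = store.add_node({"X"}, {})
        b = store.add_node({"X"}, {})
        store.add_edge(a, b, "t1")
        store.add_edge(a, b, "t2")
        assert {k for _s, _t, k, _a in store.edges(a, direction="out")} == {"t1", "t2"}

    def test_readding_same_type_edge_is_idempotent(self):
        store = PropertyGraph()
        a = store.add_node({"X"}, {})
        b = store.add_node({"X"}, {})
        store.add_edge(a, b, "t")
        store.add_edge(a, b, "t")
        assert store.n_edges == 1


class TestNeighbors:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_edge_scan(self, seed):
        store = random_property_graph(seed, n_nodes=30, n_edges=50)
        all_edges = list(store.edges())
        for node in store.node_ids():
            for edge_type in ("x", "y", g.WILDCARD):
                for direction in ("out", "in", "both"):
                    expected = set()
                    for s, t, k, _a in all_edges:
                        if edge_type != g.WILDCARD and k != edge_type:
                            continue
                        if direction in ("out", "both") and s == node:
                            expected.add(t)
                        if direction in ("in", "both") and t == node:
                            expected.add(s)
                    assert store.neighbors(node, edge_type, direction) == expected

    def test_isolated_node_has_no_neighbors(self):
        store = PropertyGraph()
        nid = store.add_node({"X"}, {})
        assert store.neighbors(nid, g.WILDCARD, "both") == set()

    def test_unknown_node_raises(self):
        with pytest.raises(IntegrityError):
            PropertyGraph().neighbors(0)


def _walk_reachable(store, start, edge_type, direction, min_hops, max_hops):
    """Independent oracle: boolean adjacency powers (walk semantics)."""
    nodes = sorted(store.node_ids())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for s, t, k, _a in store.edges():
        if edge_type != g.WILDCARD and k != edge_type:
            continue
        if direction in ("out", "both"):
            adj[idx[s]][idx[t]] = True
        if direction in ("in", "both"):
            adj[idx[t]][idx[s]] = True
    frontier = {idx[s] for s in start}
    result = set(frontier) if min_hops == 0 else set()
    current = frontier
    for depth in range(1, (max_hops if max_hops is not None else min_hops + n) + 1):
        current = {j for i in current for j in range(n) if adj[i][j]}
        if depth >= min_hops:
            result |= current
        if not current:
            break
    return {nodes[i] for i in result}


class TestTraverse:
    def test_zero_hops_is_identity(self):
        store = random_property_graph(3, 10, 15)
        start = {0, 1}
        assert store.traverse(start, g.WILDCARD, "out", 0, 0) == start

    def test_invalid_bounds_rejected(self):
        store = PropertyGraph()
        nid = store.add_node({"X"}, {})
        with pytest.raises(ValidationError):
            store.traverse([nid], "t", "out", 2, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_walk_oracle_on_random_graphs(self, seed):
        rng = random.Random(seed)
        store = random_property_graph(seed, n_nodes=rng.randint(5, 50), n_edges=rng.randint(5, 80))
        nodes = sorted(store.node_ids())
        for _ in range(5):
            start = set(rng.sample(nodes, rng.randint(1, 3)))
            lo = rng.randint(0, 2)
            hi = rng.choice([lo, lo + 1, lo + 2, None])
            et = rng.choice(["x", "y", g.WILDCARD])
            d = rng.choice(["out", "in", "both"])
            assert store.traverse(start, et, d, lo, hi) == _walk_reachable(
                store, start, et, d, lo, hi
            )

    def test_annotation_reaches_model_within_two_upward_hops(self, fixture_store):
        # both direct model annotations (1 hop) and element annotations (2 hops)
        store = fixture_store
        models = store.nodes_by_label(g.SBML_MODEL) | store.nodes_by_label(g.CELLML_MODEL)
        for ann in store.nodes_by_label(g.ANNOTATION):
            up = store.traverse([ann], g.BELONGS_TO, "out", 1, 2)
            assert up & models


class TestValidationAndPersistence:
    def test_imported_fixtures_validate(self, fixture_store):
        report = fixture_store.validate()
        assert report.unreachable == []
        assert report.multi_document == []

    def test_dump_load_roundtrip(self, tmp_path):
        store = random_property_graph(11, 25, 40)
        path = str(tmp_path / "store.json")
        store.dump(path)
        loaded = PropertyGraph.load(path)
        assert len(loaded) == len(store)
        assert loaded.n_edges == store.n_edges
        for label in ("A", "B", "C"):
            assert loaded.nodes_by_label(label) == store.nodes_by_label(label)
        assert sorted(loaded.edges()) == sorted(store.edges())

    def test_load_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValidationError):
            PropertyGraph.load(str(path))
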