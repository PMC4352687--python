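"""Query layer: pattern matching vs exhaustive oracle, aggregation,
text search ranking, and the canned repository queries."""

import itertools
import random
import statistics

import pytest

from modelgraph import PropertyGraph, PatternStep, aggregate, canned_query, match, text_search
from modelgraph import graph as g
from modelgraph.query import AggregationSpec, QueryError
from modelgraph.textindex import tokenize

from conftest import random_property_graph


# ----------------------------------------------------------------------
# match
# ----------------------------------------------------------------------
def _walks(store, source, edge_type, direction, min_hops, max_hops):
    """Exhaustive walk enumeration (oracle; no visited-set shortcuts)."""
    reached = set()
    cap = max_hops if max_hops is not None else min_hops + len(store)

    def adjacency(node):
        return store.neighbors(node, edge_type, direction)

    frontier = {source}
    if min_hops == 0:
        reached.add(source)
    seen = {(source, 0)}
    for depth in range(1, cap + 1):
        nxt = set()
        for n in frontier:
            for m in adjacency(n):
                if (m, depth) not in seen:
                    seen.add((m, depth))
                    nxt.add(m)
        if depth >= min_hops:
            reached |= nxt
        frontier = nxt
    return reached


def _oracle_match(store, pattern):
    """Enumerate all node tuples and check every step explicitly."""
    bound_steps = [s for s in pattern if not s.negated]
    nodes = sorted(store.node_ids())
    rows = []
    for combo in itertools.product(nodes, repeat=len(bound_steps)):
        ok = True
        bound_i = 0
        prev = None
        for step in pattern:
            if step.negated:
                hits = [
                    n
                    for n in _walks(store, prev, step.edge_type, step.direction,
                                    step.min_hops, step.max_hops)
                    if _attrs_ok(store, n, step)
                ]
                if hits:
                    ok = False
                    break
                continue
            node = combo[bound_i]
            bound_i += 1
            if not _attrs_ok(store, node, step):
                ok = False
                break
            if prev is not None and node not in _walks(
                store, prev, step.edge_type, step.direction, step.min_hops, step.max_hops
            ):
                ok = False
                break
            prev = node
        if ok:
            rows.append(combo)
    return sorted(rows)


def _attrs_ok(store, node, step):
    if step.node_label != g.WILDCARD and step.node_label not in store.labels(node):
        return False
    for attr, op, value in step.attribute_filters:
        actual = store.get(node, attr)
        if actual is None:
            return False
        if op == "equals" and not (actual == value or str(actual) == str(value)):
            return False
    return True


class TestMatch:
    def test_empty_store_zero_rows(self):
        result = match(PropertyGraph(), [PatternStep(node_label="A")])
        assert result.rows == []

    def test_invalid_pattern_rejected(self):
        store = PropertyGraph()
        store.add_node({"A"}, {})
        with pytest.raises(QueryError):
            match(store, [])
        with pytest.raises(QueryError):
            match(store, [PatternStep(node_label="A", min_hops=3, max_hops=1)])

    def test_components_of_named_model(self, fixture_store):
        pattern = [
            PatternStep(node_label=g.CELLML_MODEL,
                        attribute_filters=[("NAME", "equals", "tyson_1991")]),
            PatternStep(node_label=g.CELLML_COMPONENT, edge_type=g.HAS_COMPONENT),
        ]
        rows = match(fixture_store, pattern).rows
        names = {str(fixture_store.get(c, "NAME")) for _m, c in rows}
        assert names == {"YP", "Y", "M", "pM", "CP", "C2", "environment",
                         "reaction_constants"}

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_exhaustive_enumeration_on_random_graphs(self, seed):
        rng = random.Random(seed)
        store = random_property_graph(
            seed, n_nodes=rng.randint(5, 40), n_edges=rng.randint(5, 60)
        )
        pattern = [PatternStep(node_label=rng.choice(["A", "B", g.WILDCARD]))]
        for _ in range(rng.randint(1, 2)):
            lo = rng.randint(1, 2)
            pattern.append(
                PatternStep(
                    node_label=rng.choice(["A", "B", "C", g.WILDCARD]),
                    edge_type=rng.choice(["x", "y", g.WILDCARD]),
                    direction=rng.choice(["out", "in", "both"]),
                    min_hops=lo,
                    max_hops=rng.choice([lo, lo + 1]),
                    negated=rng.random() < 0.2,
                )
            )
        if all(s.negated for s in pattern[1:]):
            pattern[1].negated = False
        assert match(store, pattern).rows == _oracle_match(store, pattern)

    def test_determinism_identical_stores_identical_rows(self):
        results = []
        for _ in range(2):
            store = random_property_graph(5, 20, 30)
            pattern = [PatternStep(node_label="A"),
                       PatternStep(edge_type="x", direction="both")]
            results.append(repr(match(store, pattern).rows))
        assert results[0] == results[1]


# ----------------------------------------------------------------------
# aggregate
# ----------------------------------------------------------------------
class TestAggregate:
    def test_hand_computed_group_stats(self):
        from modelgraph.query import QueryResult

        rows = [("c1", 1), ("c2", 1), ("c2", 2), ("c3", 1), ("c3", 2), ("c3", 3)]
        base = QueryResult(columns=["component", "var"], rows=rows)
        grouped = aggregate(
            base,
            AggregationSpec(group_by=["component"],
                            aggregates=[("count", "var", "n")]),
        )
        counts = [r[1] for r in grouped.rows]
        assert counts == [1, 2, 3]
        stats = aggregate(
            grouped,
            AggregationSpec(aggregates=[("avg", "n", "avg"), ("stdev", "n", "sd")]),
        )
        assert stats.aggregates["avg"] == 2.0
        assert stats.aggregates["sd"] == 1.0

    def test_unbound_column_rejected(self):
        from modelgraph.query import QueryResult

        base = QueryResult(columns=["a"], rows=[(1,)])
        with pytest.raises(QueryError):
            aggregate(base, AggregationSpec(aggregates=[("count", "ghost", "n")]))

    def test_order_by_desc_with_limit_and_deterministic_ties(self):
        from modelgraph.query import QueryResult

        rows = [("b", 2), ("a", 2), ("c", 1)]
        base = QueryResult(columns=["NAME", "n"], rows=rows)
        out = aggregate(
            base,
            AggregationSpec(
                group_by=["NAME", "n"], aggregates=[],
                order_by=[("n", "desc"), ("NAME", "asc")], limit=1,
            ),
        )
        assert out.rows == [("a", 2)]

    @pytest.mark.parametrize("seed", range(10))
    def test_stats_equal_independent_recomputation(self, seed):
        from modelgraph.query import QueryResult

        rng = random.Random(seed)
        rows = [(rng.randint(0, 4), rng.randint(1, 100)) for _ in range(rng.randint(2, 60))]
        base = QueryResult(columns=["grp", "v"], rows=rows)
        out = aggregate(
            base,
            AggregationSpec(
                group_by=["grp"],
                aggregates=[("min", "v", "min"), ("max", "v", "max"),
                            ("avg", "v", "avg"), ("stdev", "v", "sd"),
                            ("count", "v", "n")],
            ),
        )
        for grp, vmin, vmax, vavg, vsd, n in out.rows:
            values = [v for gg, v in rows if gg == grp]
            assert vmin == min(values)
            assert vmax == max(values)
            assert vavg == pytest.approx(statistics.mean(values))
            expected_sd = statistics.stdev(values) if len(values) > 1 else 0.0
            assert vsd == pytest.approx(expected_sd)
            assert n == len(values)


# ----------------------------------------------------------------------
# text search
# ----------------------------------------------------------------------
def _text_store(descriptions):
    store = PropertyGraph()
    for i, text in enumerate(descriptions):
        store.add_node(
            {g.RESOURCE}, {"URI": f"urn:miriam:x:R{i:04d}", "KEY": f"x:R{i:04d}",
                           "RESOURCETEXT": text}
        )
    return store


class TestTextSearch:
    def test_exactly_the_token_containing_resources(self):
        rng = random.Random(0)
        phrase_docs = [f"{w} m-phase inducer phosphatase record" for w in
                       ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta")]
        decoys = [f"unrelated protein {rng.randrange(10 ** 6)} description"
                  for _ in range(20)]
        store = _text_store(phrase_docs + decoys)
        result = text_search(store, "m-phase inducer phosphatase")
        hit_uris = {row[1] for row in result.rows}
        oracle = {
            str(store.get(n, "URI"))
            for n in store.nodes_by_label(g.RESOURCE)
            if all(tok in tokenize(str(store.get(n, "RESOURCETEXT")))
                   for tok in tokenize("m-phase inducer phosphatase"))
        }
        assert hit_uris == oracle
        assert len(hit_uris) == 7

    def test_absent_token_empty_result(self):
        store = _text_store(["alpha beta", "gamma delta"])
        assert text_search(store, "omega").rows == []

    def test_term_frequency_strictly_increases_score(self):
        store = _text_store(
            ["phosphatase single mention", "phosphatase phosphatase double mention"]
        )
        result = text_search(store, "phosphatase")
        assert len(result.rows) == 2
        scores = {row[1]: row[2] for row in result.rows}
        assert scores["urn:miriam:x:R0001"] > scores["urn:miriam:x:R0000"]

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            text_search(_text_store(["a"]), "   ")


# ----------------------------------------------------------------------
# canned queries
# ----------------------------------------------------------------------
class TestCannedQueries:
    def test_unknown_name_lists_valid_ones(self, fixture_store):
        with pytest.raises(QueryError, match="list_species"):
            canned_query(fixture_store, "nope")

    def test_models_by_algorithm_returns_cellml_tyson(self, fixture_store):
        rows = canned_query(
            fixture_store, "models_by_algorithm", {"kisao": "KISAO:0000019"}
        ).rows
        assert ("tyson_1991", "tyson1991.reconstructed.sedml") in rows

    def test_simulations_for_model_two_experiments(self, fixture_store):
        rows = canned_query(
            fixture_store, "simulations_for_model", {"name": "Novak1997 - Cell Cycle"}
        ).rows
        assert len(rows) == 2
        assert {r[3] for r in rows} == {
            "novak1997_fig2a.reconstructed.sedml",
            "novak1997_fig2b.reconstructed.sedml",
        }

    def test_model_lookup_by_name(self, fixture_store):
        rows = canned_query(
            fixture_store, "model_by_name", {"name": "tyson_1991"}
        ).rows
        assert len(rows) == 1 and rows[0][1] == "tyson_1991"

    def test_closure_count_decomposes_into_direct_plus_descendants(self):
        # 3 resources on the parent concept, 2 on a child
        store = PropertyGraph()
        import io
        from modelgraph.ontology import OntologyImporter
        from modelgraph.synthetic import build_obo
        from modelgraph.linking import link_annotations_to_ontology

        terms = [("W:0000001", "parent", "", []), ("W:0000002", "child", "", ["W:0000001"])]
        OntologyImporter(store).import_file(io.BytesIO(build_obo("W", terms).encode()), "W")
        ann = store.add_node({g.ANNOTATION}, {})
        doc = store.add_node({g.DOCUMENT}, {"FILENAME": "f"})
        store.add_edge(ann, doc, g.BELONGS_TO)
        uses = [("W%3A0000001", 3), ("W%3A0000002", 2)]
        for acc, n in uses:
            res = store.add_node(
                {g.RESOURCE}, {"URI": f"urn:miriam:w:{acc}", "KEY": acc, "RESOURCETEXT": ""}
            )
            for k in range(n):
                a = store.add_node({g.ANNOTATION}, {})
                store.add_edge(a, doc, g.BELONGS_TO)
                store.add_edge(a, res, "is")
                store.add_edge(res, a, g.BELONGS_TO)
        link_annotations_to_ontology(store, "W")
        out = canned_query(
            store, "annotation_count_with_descendants", {"concept_id": "W:0000001"}
        ).aggregates
        assert out == {"total": 5, "direct": 3}

    def test_experiments_observing_matches_three_filter_oracle(self, fixture_store):
        store = fixture_store
        result = canned_query(
            store, "experiments_observing",
            {"phrase": "m-phase inducer phosphatase", "qualifier": "is",
             "role": g.IS_MODIFIER},
        )
        # oracle: brute-force scan over all OBSERVES edges with explicit checks
        tokens = tokenize("m-phase inducer phosphatase")
        expected = set()
        for s, t, k, _a in store.edges():
            if k != g.OBSERVES:
                continue
            sp = t
            if g.SBML_SPECIES not in store.labels(sp):
                continue
            has_role = any(
                k2 == g.IS_MODIFIER for _s2, _t2, k2, _a2 in store.edges(sp, direction="out")
            )
            if not has_role:
                continue
            qualified = False
            for ann in store.neighbors(sp, g.HAS_ANNOTATION, "out"):
                for _sa, res, k3, _aa in store.edges(ann, direction="out"):
                    if k3 != "is" or g.RESOURCE not in store.labels(res):
                        continue
                    text = tokenize(str(store.get(res, "RESOURCETEXT", "")))
                    if all(tok in text for tok in tokens):
                        qualified = True
            if qualified:
                docs = [
                    d for d in store.traverse([s], g.BELONGS_TO, "out", 1, None)
                    if g.DOCUMENT in store.labels(d)
                ]
                for d in docs:
                    expected.add((str(store.get(d, "FILENAME")), str(store.get(sp, "NAME"))))
        got = {(row[0], row[3]) for row in result.rows}
        assert got == expected
        assert expected  # the fixture corpus does exercise the query

    def test_q1_needs_all_three_conditions(self, fixture_store):
        rows = canned_query(fixture_store, "species_only_modifier_top", {"n": 3}).rows
        top_model, top_species, top_count = rows[0]
        assert (top_model, top_species, top_count) == (
            "Schaber2012 - Hog pathway in yeast", "Hog1PPActive", 10
        )
        # runner-up is the weaker pure modifier, not the reactant-entangled one
        assert rows[1][2] < 10
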