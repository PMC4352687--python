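"""Pattern matching, aggregation, statistics and index-backed search.

The query layer is a programmatic API, not a query-language parser: a
linear chain of :class:`PatternStep` objects plays the role of a MATCH
clause (index-seeded on the first step's label, traversal afterwards),
:func:`aggregate` covers count/min/max/avg/stdev/collect with ORDER BY
and LIMIT, and :func:`text_search` answers ranked full-text look-ups
against resource description text.  On top of these, ``canned_query``
exposes the named queries a model repository actually needs (list
species of a model, experiments observing an annotated modifier,
annotation statistics, ...).

All row orders are deterministic (sorted by node id or stated sort
keys), so identical stores yield identical serialized results.
Standard deviations are sample standard deviations (n-1 denominator);
a single observation reports 0.0.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from typing import Any, Callable

from . import graph as g
from .graph import WILDCARD
from .ontology import descendant_nodes


class QueryError(g.GraphError):
    """Invalid pattern, unknown canned query, or bad aggregation spec."""


@dataclass
class PatternStep:
    """One hop of a linear match pattern.

    The first step of a pattern only uses ``node_label`` and
    ``attribute_filters``; later steps traverse ``edge_type`` in
    ``direction`` for ``min_hops..max_hops`` hops (``None`` = unbounded)
    and then filter the reached node.  A ``negated`` step asserts that
    no such node exists and binds nothing.
    """

    node_label: str = WILDCARD
    edge_type: str = WILDCARD
    direction: str = "out"
    min_hops: int = 1
    max_hops: int | None = 1
    attribute_filters: list[tuple[str, str, Any]] = field(default_factory=list)
    negated: bool = False


@dataclass
class QueryResult:
    columns: list[str]
    rows: list[tuple]
    aggregates: dict[str, Any] = field(default_factory=dict)
    ranking_scores: dict[int, float] | None = None


def _node_matches(store: g.PropertyGraph, nid: int, step: PatternStep) -> bool:
    if step.node_label != WILDCARD and step.node_label not in store.labels(nid):
        return False
    for attr, op, value in step.attribute_filters:
        actual = store.get(nid, attr)
        if actual is None:
            return False
        text = str(actual)
        if op == "equals":
            ok = actual == value or text == str(value)
        elif op == "regex":
            ok = re.search(str(value), text) is not None  # unanchored, case-sensitive
        elif op == "contains":
            ok = str(value) in text
        else:
            raise QueryError(f"unknown attribute operator {op!r}")
        if not ok:
            return False
    return True


def match(store: g.PropertyGraph, pattern: list[PatternStep]) -> QueryResult:
    """All binding tuples satisfying the pattern, sorted by node ids."""
    if not pattern:
        raise QueryError("empty pattern")
    if pattern[0].negated:
        raise QueryError("the first pattern step cannot be negated")
    for step in pattern:
        if step.min_hops < 0 or (
            step.max_hops is not None and step.min_hops > step.max_hops
        ):
            raise QueryError("invalid hop bounds")
    first = pattern[0]
    if first.node_label == WILDCARD:
        candidates = sorted(store.node_ids())
    else:
        candidates = sorted(store.nodes_by_label(first.node_label))
    rows: list[tuple] = []

    def extend(prefix: tuple, steps: list[PatternStep]) -> None:
        if not steps:
            rows.append(prefix)
            return
        step = steps[0]
        reached = store.traverse(
            [prefix[-1]], step.edge_type, step.direction, step.min_hops, step.max_hops
        )
        hits = sorted(n for n in reached if _node_matches(store, n, step))
        if step.negated:
            if not hits:
                extend(prefix, steps[1:])
            return
        for n in hits:
            extend(prefix + (n,), steps[1:])

    for nid in candidates:
        if _node_matches(store, nid, first):
            extend((nid,), pattern[1:])
    n_bound = 1 + sum(1 for s in pattern[1:] if not s.negated)
    return QueryResult(columns=[f"n{i}" for i in range(n_bound)], rows=rows)


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------
@dataclass
class AggregationSpec:
    group_by: list[str] = field(default_factory=list)
    aggregates: list[tuple[str, str, str]] = field(default_factory=list)  # (op, column, alias)
    order_by: list[tuple[str, str]] = field(default_factory=list)  # (column, asc|desc)
    limit: int | None = None


def _stdev(values: list[float]) -> float:
    return statistics.stdev(values) if len(values) > 1 else 0.0


_AGG_OPS: dict[str, Callable[[list], Any]] = {
    "count": len,
    "min": min,
    "max": max,
    "avg": lambda v: statistics.mean(v),
    "stdev": _stdev,
    "collect": lambda v: tuple(sorted(set(v), key=str)),
}


def aggregate(result: QueryResult, spec: AggregationSpec) -> QueryResult:
    """Grouped aggregation over a result's rows."""
    col_idx = {name: i for i, name in enumerate(result.columns)}
    for name in spec.group_by + [c for _op, c, _a in spec.aggregates if c != "*"]:
        if name not in col_idx:
            raise QueryError(f"aggregate over unbound column {name!r}")
    for op, _c, _a in spec.aggregates:
        if op not in _AGG_OPS:
            raise QueryError(f"unknown aggregation op {op!r}")

    groups: dict[tuple, list[tuple]] = {}
    for row in result.rows:
        key = tuple(row[col_idx[c]] for c in spec.group_by)
        groups.setdefault(key, []).append(row)

    out_columns = list(spec.group_by) + [alias for _op, _c, alias in spec.aggregates]
    out_rows = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        rows = groups[key]
        values = []
        for op, column, _alias in spec.aggregates:
            if column == "*":
                col_values = list(rows)
            else:
                col_values = [r[col_idx[column]] for r in rows]
            values.append(_AGG_OPS[op](col_values))
        out_rows.append(key + tuple(values))

    out_idx = {name: i for i, name in enumerate(out_columns)}
    if spec.order_by:
        for column, order in reversed(spec.order_by):
            if column not in out_idx:
                raise QueryError(f"ORDER BY unknown column {column!r}")
            out_rows.sort(
                key=lambda r: r[out_idx[column]], reverse=(order == "desc")
            )
    if spec.limit is not None:
        out_rows = out_rows[: spec.limit]
    aggregates = {}
    if not spec.group_by and len(out_rows) == 1:
        aggregates = dict(zip(out_columns, out_rows[0]))
    return QueryResult(columns=out_columns, rows=out_rows, aggregates=aggregates)


# ----------------------------------------------------------------------
# text search
# ----------------------------------------------------------------------
def text_search(store: g.PropertyGraph, index_query: str) -> QueryResult:
    """Resources whose description contains all query tokens, ranked.

    TF-IDF scoring, descending; ties broken by URI.
    """
    hits = store.text_index().search(index_query)
    decorated = sorted(
        ((nid, score, str(store.get(nid, "URI", ""))) for nid, score in hits),
        key=lambda t: (-t[1], t[2]),
    )
    return QueryResult(
        columns=["resource", "URI", "score"],
        rows=[(nid, uri, score) for nid, score, uri in decorated],
        ranking_scores={nid: score for nid, score, _uri in decorated},
    )


# ----------------------------------------------------------------------
# canned queries
# ----------------------------------------------------------------------
def _model_of(store: g.PropertyGraph, node: int, label: str) -> int | None:
    for m in sorted(store.neighbors(node, g.BELONGS_TO, "out")):
        if label in store.labels(m):
            return m
    return None


def _document_of(store: g.PropertyGraph, node: int, hops: tuple[int, int | None]) -> int | None:
    docs = store.traverse([node], g.BELONGS_TO, "out", hops[0], hops[1])
    docs = [d for d in docs if g.DOCUMENT in store.labels(d)]
    return min(docs) if docs else None


def species_only_modifier_top(store: g.PropertyGraph, n: int = 1) -> QueryResult:
    """Species acting only as modifiers, ranked by modified reactions."""
    rows = []
    for sp in sorted(store.nodes_by_label(g.SBML_SPECIES)):
        n_mod = sum(1 for _ in store.edges(sp, g.IS_MODIFIER, "out"))
        if n_mod == 0:
            continue
        if store.neighbors(sp, g.IS_REACTANT, "out") or store.neighbors(
            sp, g.IS_PRODUCT, "out"
        ):
            continue
        model = _model_of(store, sp, g.SBML_MODEL)
        rows.append(
            (
                str(store.get(model, "NAME", "")) if model is not None else "",
                str(store.get(sp, "NAME", "")),
                n_mod,
            )
        )
    rows.sort(key=lambda r: (-r[2], r[1], r[0]))
    return QueryResult(columns=["model", "species", "numOfMod"], rows=rows[:n])


def simulations_for_model(store: g.PropertyGraph, name: str) -> QueryResult:
    rows = []
    for label in (g.SBML_MODEL, g.CELLML_MODEL):
        for m in sorted(store.nodes_by_attribute(label, "NAME", name)):
            for ref in sorted(store.neighbors(m, g.REFERENCES_SIMULATION_MODEL, "in")):
                doc = _document_of(store, ref, (2, 2))
                rows.append(
                    (
                        str(store.get(m, "NAME", "")),
                        str(store.get(m, "ID", "")),
                        str(store.get(ref, "MODELSOURCE", "")),
                        str(store.get(doc, "FILENAME", "")) if doc is not None else "",
                    )
                )
    return QueryResult(columns=["Model", "ModelID", "ModelSource", "SEDMLFile"], rows=rows)


def models_by_algorithm(
    store: g.PropertyGraph, kisao: str, format_label: str = g.CELLML_MODEL
) -> QueryResult:
    rows = set()
    for sim in store.nodes_by_attribute(g.SEDML_SIMULATION, "SIMKISAO", kisao):
        doc = _document_of(store, sim, (2, 2))
        for ref in store.neighbors(sim, g.SIMULATES, "out"):
            for m in store.neighbors(ref, g.REFERENCES_SIMULATION_MODEL, "out"):
                if format_label in store.labels(m):
                    rows.add(
                        (
                            str(store.get(m, "NAME", "")),
                            str(store.get(doc, "FILENAME", "")) if doc is not None else "",
                        )
                    )
    return QueryResult(columns=["Model", "SEDMLFile"], rows=sorted(rows))


def experiments_observing(
    store: g.PropertyGraph,
    phrase: str,
    qualifier: str = "is",
    role: str = g.IS_MODIFIER,
) -> QueryResult:
    """Simulation experiments observing an annotated species in a role.

    Three filters hold simultaneously: the species is the target of an
    OBSERVES edge, carries a ``qualifier`` edge to a resource matching
    the indexed phrase, and has the requested reaction-role edge.
    """
    rows = set()
    for res, _uri, _score in text_search(store, phrase).rows:
        for ann in store.neighbors(res, g.BELONGS_TO, "out"):
            if not store.has_edge(ann, res, qualifier):
                continue
            for sp in store.neighbors(ann, g.BELONGS_TO, "out"):
                if g.SBML_SPECIES not in store.labels(sp):
                    continue
                if not store.neighbors(sp, role, "out"):
                    continue
                model = _model_of(store, sp, g.SBML_MODEL)
                for obs in store.neighbors(sp, g.OBSERVES, "in"):
                    doc = _document_of(store, obs, (1, None))
                    rows.add(
                        (
                            str(store.get(doc, "FILENAME", "")) if doc is not None else "",
                            str(store.get(model, "NAME", "")) if model is not None else "",
                            str(store.get(res, "URI", "")),
                            str(store.get(sp, "NAME", "")),
                            str(store.get(obs, "TARGET", "")),
                        )
                    )
    return QueryResult(
        columns=["SEDML", "Model", "Resource", "Species", "Target"], rows=sorted(rows)
    )


def top_annotations(store: g.PropertyGraph, n: int = 3) -> QueryResult:
    """Most frequently used annotation resources."""
    rows = []
    for res in sorted(store.nodes_by_label(g.RESOURCE)):
        count = sum(1 for _ in store.edges(res, g.BELONGS_TO, "out"))
        if count:
            rows.append((str(store.get(res, "URI", "")), count))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return QueryResult(columns=["Annotation", "AnnotationCount"], rows=rows[:n])


def annotation_count_with_descendants(store: g.PropertyGraph, concept_id: str) -> QueryResult:
    """Annotations pointing at a concept or any of its descendants."""
    closure = descendant_nodes(store, concept_id)
    from .ontology import find_concept

    root = find_concept(store, concept_id)
    total = direct = 0
    for concept in closure:
        for res in store.neighbors(concept, g.IS_ONTOLOGY_ENTRY, "in"):
            uses = sum(
                1
                for _s, _t, k, _a in store.edges(res, WILDCARD, "in")
                if k not in (g.IS_ONTOLOGY_ENTRY,)
            )
            total += uses
            if concept == root:
                direct += uses
    result = QueryResult(columns=["total", "direct"], rows=[(total, direct)])
    result.aggregates = {"total": total, "direct": direct}
    return result


def annotation_stats_per_model(
    store: g.PropertyGraph, format_label: str = g.SBML_MODEL
) -> QueryResult:
    """Min/max/avg/stdev of annotations per model (annotated models only)."""
    per_model = []
    for m in sorted(store.nodes_by_label(format_label)):
        anns = [
            a
            for a in store.traverse([m], g.BELONGS_TO, "in", 1, 2)
            if g.ANNOTATION in store.labels(a)
        ]
        count = sum(
            1
            for a in anns
            for r in store.neighbors(a, g.BELONGS_TO, "in")
            if g.RESOURCE in store.labels(r)
        )
        if count:
            per_model.append((m, count))
    base = QueryResult(columns=["model", "NumberOfAnnotation"], rows=per_model)
    return aggregate(
        base,
        AggregationSpec(
            aggregates=[
                ("max", "NumberOfAnnotation", "max"),
                ("min", "NumberOfAnnotation", "min"),
                ("avg", "NumberOfAnnotation", "avg"),
                ("stdev", "NumberOfAnnotation", "stdev"),
            ]
        ),
    )


def list_species(store: g.PropertyGraph, model_id: str) -> QueryResult:
    rows = []
    for m in sorted(store.nodes_by_attribute(g.SBML_MODEL, "ID", model_id)):
        for sp in sorted(store.neighbors(m, g.HAS_SPECIES, "out")):
            rows.append((str(store.get(sp, "ID", "")), str(store.get(sp, "NAME", ""))))
    return QueryResult(columns=["SpeciesID", "SpeciesName"], rows=rows)


def element_annotations(store: g.PropertyGraph, model_id: str) -> QueryResult:
    """Per-element annotation URIs for one model (with totals)."""
    per_element: dict[int, list[str]] = {}
    for m in sorted(store.nodes_by_attribute(g.SBML_MODEL, "ID", model_id)):
        for res in sorted(store.nodes_by_label(g.RESOURCE)):
            for ann in store.neighbors(res, g.BELONGS_TO, "out"):
                if g.ANNOTATION not in store.labels(ann):
                    continue
                for elem in store.neighbors(ann, g.BELONGS_TO, "out"):
                    if elem == m:
                        continue  # model-level annotation is not an element row
                    if m in store.neighbors(elem, g.BELONGS_TO, "out"):
                        per_element.setdefault(elem, []).append(
                            str(store.get(res, "URI", ""))
                        )
    rows = [
        (
            str(store.get(elem, "ID", "")),
            tuple(sorted(store.labels(elem))),
            tuple(sorted(uris)),
        )
        for elem, uris in sorted(per_element.items())
    ]
    result = QueryResult(columns=["Element", "ElementType", "ElementAnnotation"], rows=rows)
    result.aggregates = {
        "n_elements": len(rows),
        "n_annotations": sum(len(uris) for _e, _t, uris in rows),
    }
    return result


def elements_annotated_with(store: g.PropertyGraph, uri_regex: str) -> QueryResult:
    """Model elements annotated with resources matching a URI regex."""
    pattern = re.compile(uri_regex)
    grouped: dict[tuple[str, str, str], set[str]] = {}
    for res in sorted(store.nodes_by_label(g.RESOURCE)):
        uri = str(store.get(res, "URI", ""))
        if not pattern.search(uri):
            continue
        for ann, _res, qualifier, _attrs in (
            (s, t, k, a) for s, t, k, a in store.edges(res, WILDCARD, "in")
            if k != g.HAS_ANNOTATION
        ):
            if g.ANNOTATION not in store.labels(ann):
                continue
            for elem in store.neighbors(ann, g.BELONGS_TO, "out"):
                for m in store.neighbors(elem, g.BELONGS_TO, "out"):
                    if g.SBML_MODEL in store.labels(m) or g.CELLML_MODEL in store.labels(m):
                        key = (str(store.get(m, "ID", "")), qualifier, uri)
                        grouped.setdefault(key, set()).add(str(store.get(elem, "ID", "")))
    rows = [
        (model_id, tuple(sorted(elements)), qualifier, uri)
        for (model_id, qualifier, uri), elements in sorted(grouped.items())
    ]
    return QueryResult(columns=["ModelID", "ElementIDs", "Qualifier", "URI"], rows=rows)


def list_models_by_format(store: g.PropertyGraph, format_label: str = g.CELLML_MODEL) -> QueryResult:
    rows = [
        (m, str(store.get(m, "NAME", "")))
        for m in sorted(store.nodes_by_label(format_label))
    ]
    return QueryResult(columns=["model", "NAME"], rows=rows)


def model_by_name(
    store: g.PropertyGraph, name: str, format_label: str = g.CELLML_MODEL
) -> QueryResult:
    rows = [
        (m, str(store.get(m, "NAME", "")))
        for m in sorted(store.nodes_by_attribute(format_label, "NAME", name))
    ]
    return QueryResult(columns=["model", "NAME"], rows=rows)


def list_components(store: g.PropertyGraph, model_name: str) -> QueryResult:
    rows = []
    for m in sorted(store.nodes_by_attribute(g.CELLML_MODEL, "NAME", model_name)):
        for c in sorted(store.neighbors(m, g.HAS_COMPONENT, "out")):
            rows.append((str(store.get(c, "NAME", "")),))
    return QueryResult(columns=["ComponentName"], rows=rows)


def count_variables(store: g.PropertyGraph, model_name: str) -> QueryResult:
    count = 0
    for m in sorted(store.nodes_by_attribute(g.CELLML_MODEL, "NAME", model_name)):
        for c in store.neighbors(m, g.HAS_COMPONENT, "out"):
            count += len(store.neighbors(c, g.HAS_VARIABLE, "out"))
    result = QueryResult(columns=["count"], rows=[(count,)])
    result.aggregates = {"count": count}
    return result


def variables_per_component_stats(store: g.PropertyGraph) -> QueryResult:
    """Variables-per-component statistics over all CellML models."""
    per_component = []
    for c in sorted(store.nodes_by_label(g.CELLML_COMPONENT)):
        n = len(store.neighbors(c, g.HAS_VARIABLE, "out"))
        if n:
            per_component.append((c, n))
    base = QueryResult(columns=["component", "NumOfVar"], rows=per_component)
    return aggregate(
        base,
        AggregationSpec(
            aggregates=[
                ("min", "NumOfVar", "min"),
                ("max", "NumOfVar", "max"),
                ("avg", "NumOfVar", "avg"),
                ("stdev", "NumOfVar", "stdev"),
            ]
        ),
    )


def annotation_index_lookup(store: g.PropertyGraph, phrase: str) -> QueryResult:
    return text_search(store, phrase)


_CANNED: dict[str, Callable[..., QueryResult]] = {
    "species_only_modifier_top": species_only_modifier_top,
    "simulations_for_model": simulations_for_model,
    "models_by_algorithm": models_by_algorithm,
    "experiments_observing": experiments_observing,
    "top_annotations": top_annotations,
    "annotation_count_with_descendants": annotation_count_with_descendants,
    "annotation_stats_per_model": annotation_stats_per_model,
    "list_species": list_species,
    "element_annotations": element_annotations,
    "elements_annotated_with": elements_annotated_with,
    "list_models_by_format": list_models_by_format,
    "model_by_name": model_by_name,
    "list_components": list_components,
    "count_variables": count_variables,
    "variables_per_component_stats": variables_per_component_stats,
    "annotation_index_lookup": annotation_index_lookup,
}


def canned_query(store: g.PropertyGraph, name: str, params: dict[str, Any] | None = None) -> QueryResult:
    """Run a registered named query; unknown names list the valid set."""
    if name not in _CANNED:
        valid = ", ".join(sorted(_CANNED))
        raise QueryError(f"unknown canned query {name!r}; valid names: {valid}")
    return _CANNED[name](store, **(params or {}))
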