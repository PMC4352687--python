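"""Embedded property graph with label, attribute and full-text indices.

The store keeps labelled nodes and typed, directed edges, mirroring how
systems-biology model repositories hold heterogeneous, highly linked
meta-data: every importer (SBML, CellML, SED-ML, ontologies) writes into
one :class:`PropertyGraph`, and the query layer reads from it.

Conventions baked into the schema:

* every imported file gets a ``DOCUMENT`` root node;
* all upward (child -> parent) edges use the single type ``BELONGS_TO``,
  so variable-length upward traversals behave uniformly;
* external resources (ontology terms, protein records, publications) are
  deduplicated ``RESOURCE`` nodes shared between documents.

Storage is backed by :class:`networkx.MultiDiGraph`; parallel edges
between the same pair of nodes are keyed by edge type, so re-adding an
edge of an existing type is idempotent (its attributes are refreshed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

import networkx as nx

from .textindex import TextIndex

WILDCARD = "*"

STORE_FORMAT = "modelgraph-store"
STORE_VERSION = 1

# Label vocabulary used across the importers.
DOCUMENT = "DOCUMENT"
SBML_MODEL = "SBML_MODEL"
SBML_SPECIES = "SBML_SPECIES"
SBML_REACTION = "SBML_REACTION"
SBML_COMPARTMENT = "SBML_COMPARTMENT"
SBML_PARAMETER = "SBML_PARAMETER"
SBML_FUNCTION = "SBML_FUNCTION"
SBML_ELEMENT = "SBML_ELEMENT"
CELLML_MODEL = "CELLML_MODEL"
CELLML_COMPONENT = "CELLMLCOMPONENT"
CELLML_VARIABLE = "CELLMLVARIABLE"
SEDML_DOCUMENT = "SEDML"
SEDML_SIMULATION = "SEDML_SIMULATION"
SEDML_MODELREFERENCE = "SEDML_MODELREFERENCE"
SEDML_DATAGENERATOR = "SEDML_DATAGENERATOR"
SEDML_VARIABLE = "SEDML_VARIABLE"
SEDML_CHANGE = "SEDML_CHANGE"
ANNOTATION = "ANNOTATION"
RESOURCE = "RESOURCE"
PUBLICATION = "PUBLICATION"
ONTOLOGY_ROOT = "ONTOLOGY_ROOT"

# Edge vocabulary.
HAS_MODEL = "hasModel"
HAS_SPECIES = "hasSpecies"
HAS_REACTION = "hasReaction"
HAS_COMPARTMENT = "hasCompartment"
HAS_PARAMETER = "hasParameter"
HAS_FUNCTION = "hasFunction"
HAS_COMPONENT = "hasComponent"
HAS_VARIABLE = "hasVariable"
HAS_ANNOTATION = "hasAnnotation"
BELONGS_TO = "BELONGS_TO"
IS_CONTAINED_IN = "isContainedIn"
IS_REACTANT = "IS_REACTANT"
IS_PRODUCT = "IS_PRODUCT"
IS_MODIFIER = "IS_MODIFIER"
IS_ONTOLOGY_ENTRY = "IS_ONTOLOGY_ENTRY"
IS_A = "isA"
SIMULATES = "SIMULATES"
REFERENCES_SIMULATION_MODEL = "REFERENCES_SIMULATION_MODEL"
OBSERVES = "OBSERVES"
MAPPED_TO = "MAPPED_TO"
IS_SIMILAR_TO = "IS_SIMILAR_TO"

#: labels whose nodes are exempt from the one-document upward-reachability
#: rule (shared between documents, or not part of any document).
_SHARED_LABELS = {RESOURCE, PUBLICATION, ONTOLOGY_ROOT}


class GraphError(Exception):
    """Base class for store errors."""


class ValidationError(GraphError):
    """Invalid input to a store operation."""


class IntegrityError(GraphError):
    """Referential-integrity violation (unknown endpoint, missing node)."""


@dataclass
class ValidationReport:
    """Outcome of :meth:`PropertyGraph.validate`."""

    self_edges: list[tuple[int, str]] = field(default_factory=list)
    unreachable: list[int] = field(default_factory=list)
    multi_document: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unreachable and not self.multi_document


class PropertyGraph:
    """Labelled property graph with secondary indices.

    Node ids are store-assigned monotonically increasing integers; they
    are stable within a session but not across re-imports.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._next_id = 0
        self._label_index: dict[str, set[int]] = {}
        self._attr_index: dict[tuple[str, str], dict[Any, set[int]]] = {}
        self._text_index: TextIndex | None = None

    # ------------------------------------------------------------------
    # mutation
    # ------------------------------------------------------------------
    def add_node(self, labels: Iterable[str], attributes: dict[str, Any] | None = None) -> int:
        labels = frozenset(labels)
        if not labels:
            raise ValidationError("a node needs at least one label")
        attributes = dict(attributes or {})
        nid = self._next_id
        self._next_id += 1
        self._g.add_node(nid, labels=labels, attributes=attributes)
        for label in labels:
            self._label_index.setdefault(label, set()).add(nid)
            for name, value in attributes.items():
                self._attr_index.setdefault((label, name), {}).setdefault(value, set()).add(nid)
        self._text_index = None
        return nid

    def add_edge(
        self,
        source: int,
        target: int,
        edge_type: str,
        attributes: dict[str, Any] | None = None,
    ) -> tuple[int, int, str]:
        for endpoint in (source, target):
            if endpoint not in self._g:
                raise IntegrityError(f"unknown node id {endpoint!r}")
        if not edge_type:
            raise ValidationError("edge_type must be non-empty")
        self._g.add_edge(source, target, key=edge_type, attributes=dict(attributes or {}))
        return (source, target, edge_type)

    def set_attribute(self, node: int, name: str, value: Any) -> None:
        data = self._node_data(node)
        old = data["attributes"].get(name)
        if old is not None:
            for label in data["labels"]:
                bucket = self._attr_index.get((label, name), {}).get(old)
                if bucket:
                    bucket.discard(node)
        data["attributes"][name] = value
        for label in data["labels"]:
            self._attr_index.setdefault((label, name), {}).setdefault(value, set()).add(node)
        self._text_index = None

    # ------------------------------------------------------------------
    # inspection
    # ------------------------------------------------------------------
    def __contains__(self, node: int) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_ids(self) -> Iterator[int]:
        return iter(self._g.nodes)

    def labels(self, node: int) -> frozenset[str]:
        return self._node_data(node)["labels"]

    def attributes(self, node: int) -> dict[str, Any]:
        return self._node_data(node)["attributes"]

    def get(self, node: int, name: str, default: Any = None) -> Any:
        return self._node_data(node)["attributes"].get(name, default)

    def _node_data(self, node: int) -> dict:
        try:
            return self._g.nodes[node]
        except KeyError:
            raise IntegrityError(f"unknown node id {node!r}") from None

    # ------------------------------------------------------------------
    # index lookups
    # ------------------------------------------------------------------
    def nodes_by_label(self, label: str) -> set[int]:
        return set(self._label_index.get(label, ()))

    def nodes_by_attribute(self, label: str, name: str, value: Any) -> set[int]:
        return set(self._attr_index.get((label, name), {}).get(value, ()))

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def edges(
        self,
        node: int | None = None,
        edge_type: str = WILDCARD,
        direction: str = "out",
    ) -> Iterator[tuple[int, int, str, dict[str, Any]]]:
        """Iterate ``(source, target, type, attributes)`` tuples.

        With ``node=None`` all edges are yielded (``direction`` ignored).
        """
        if node is None:
            it = self._g.edges(keys=True, data="attributes")
            for s, t, k, a in it:
                if edge_type == WILDCARD or k == edge_type:
                    yield (s, t, k, a)
            return
        self._node_data(node)
        dirs = ("out", "in") if direction == "both" else (direction,)
        for d in dirs:
            if d == "out":
                it = self._g.out_edges(node, keys=True, data="attributes")
            elif d == "in":
                it = self._g.in_edges(node, keys=True, data="attributes")
            else:
                raise ValidationError(f"direction must be out|in|both, got {d!r}")
            for s, t, k, a in it:
                if edge_type == WILDCARD or k == edge_type:
                    yield (s, t, k, a)

    def has_edge(self, source: int, target: int, edge_type: str) -> bool:
        return self._g.has_edge(source, target, key=edge_type)

    def edge_attributes(self, source: int, target: int, edge_type: str) -> dict[str, Any]:
        try:
            return self._g.edges[source, target, edge_type]["attributes"]
        except KeyError:
            raise IntegrityError(f"no {edge_type} edge {source}->{target}") from None

    def neighbors(self, node: int, edge_type: str = WILDCARD, direction: str = "out") -> set[int]:
        """Nodes adjacent via exactly one edge of the given type/direction."""
        out = set()
        for s, t, _k, _a in self.edges(node, edge_type, direction):
            out.add(t if s == node else s)
            if s == node and t == node:
                out.add(node)
        return out

    def traverse(
        self,
        start: Iterable[int],
        edge_type: str = WILDCARD,
        direction: str = "out",
        min_hops: int = 1,
        max_hops: int | None = 1,
    ) -> set[int]:
        """All nodes reachable in ``[min_hops, max_hops]`` hops.

        ``max_hops=None`` means unbounded (the ``*`` of a variable-length
        path).  Walk semantics: a node qualifies if *some* walk of a
        length in range reaches it, which matches variable-length path
        matching; cycles are handled by visiting ``(node, depth)`` pairs,
        with the unbounded depth capped at ``min_hops + |V|`` (any longer
        walk can be cycle-shortened into that window).
        """
        start = set(start)
        for node in start:
            self._node_data(node)
        if min_hops < 0:
            raise ValidationError("min_hops must be >= 0")
        if max_hops is not None and min_hops > max_hops:
            raise ValidationError("min_hops must not exceed max_hops")
        cap = max_hops if max_hops is not None else min_hops + len(self._g)
        result: set[int] = set(start) if min_hops == 0 else set()
        seen: set[tuple[int, int]] = {(n, 0) for n in start}
        frontier = start
        depth = 0
        while frontier and depth < cap:
            depth += 1
            nxt: set[int] = set()
            for node in frontier:
                for nb in self.neighbors(node, edge_type, direction):
                    if (nb, depth) not in seen:
                        seen.add((nb, depth))
                        nxt.add(nb)
            if depth >= min_hops:
                result |= nxt
            frontier = nxt
        return result

    # ------------------------------------------------------------------
    # full-text index
    # ------------------------------------------------------------------
    def text_index(self) -> TextIndex:
        """TF-IDF index over RESOURCE description text (rebuilt lazily)."""
        if self._text_index is None:
            idx = TextIndex()
            for nid in sorted(self.nodes_by_label(RESOURCE)):
                text = self.get(nid, "RESOURCETEXT")
                if text:
                    idx.add(nid, str(text))
            idx.freeze()
            self._text_index = idx
        return self._text_index

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> ValidationReport:
        """Check structural invariants after an import.

        Every node that belongs to a document (i.e. is not itself a
        DOCUMENT, an ontology concept, or a shared RESOURCE/PUBLICATION
        node) must reach exactly one DOCUMENT root along BELONGS_TO.
        """
        report = ValidationReport()
        for s, t, k, _a in self.edges():
            if s == t:
                report.self_edges.append((s, k))
        documents = self.nodes_by_label(DOCUMENT)
        for nid in self._g.nodes:
            labels = self.labels(nid)
            if DOCUMENT in labels or labels & _SHARED_LABELS:
                continue
            if any(lab.endswith("Ontology") for lab in labels):
                continue
            reached = self.traverse([nid], BELONGS_TO, "out", 1, None) & documents
            if not reached:
                report.unreachable.append(nid)
            elif len(reached) > 1:
                report.multi_document.append(nid)
        return report

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def dump(self, path: str) -> None:
        """Serialize to a single JSON file (indices rebuilt on load)."""
        payload = {
            "format": STORE_FORMAT,
            "version": STORE_VERSION,
            "next_id": self._next_id,
            "nodes": [
                {
                    "id": nid,
                    "labels": sorted(self.labels(nid)),
                    "attributes": self.attributes(nid),
                }
                for nid in sorted(self._g.nodes)
            ],
            "edges": [
                {"source": s, "target": t, "type": k, "attributes": a}
                for s, t, k, a in sorted(
                    self.edges(), key=lambda e: (e[0], e[1], e[2])
                )
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "PropertyGraph":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != STORE_FORMAT:
            raise ValidationError(f"{path}: not a {STORE_FORMAT} file")
        if payload.get("version") != STORE_VERSION:
            raise ValidationError(f"{path}: unsupported store version")
        store = cls()
        for rec in payload["nodes"]:
            nid = rec["id"]
            store._g.add_node(nid, labels=frozenset(rec["labels"]), attributes=rec["attributes"])
            for label in rec["labels"]:
                store._label_index.setdefault(label, set()).add(nid)
                for name, value in rec["attributes"].items():
                    store._attr_index.setdefault((label, name), {}).setdefault(value, set()).add(nid)
        store._next_id = payload.get("next_id", (max(store._g.nodes, default=-1) + 1))
        for rec in payload["edges"]:
            store.add_edge(rec["source"], rec["target"], rec["type"], rec["attributes"])
        return store
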