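"""Generic bio-ontology importer (SBO, GO, KiSAO, ...).

Concepts become nodes labelled ``<tag>Ontology`` (so e.g. every SBO term
carries the label ``SBOOntology``), with ``id``, ``LABEL`` and
``DEFINITION`` attributes; subsumption becomes ``isA`` edges from child
to parent.  An ontology root node (label ONTOLOGY_ROOT, attribute TAG)
anchors each imported ontology; every concept points to it via
BELONGS_TO.  Definitions feed the resource text index once annotations
are linked to concepts.

Accepted formats: OBO 1.2 flat files (via obonet) and a pragmatic
OWL RDF/XML subset (named classes, rdfs:label, rdfs:subClassOf between
named classes, IAO:0000115 definitions).  Only isA relations are
mapped; other relationship types are dropped and counted.  The isA
graph must be acyclic.
"""

from __future__ import annotations

import io
from typing import IO

import networkx as nx
import obonet
from lxml import etree

from . import graph as g

_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
_RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
_OWL_NS = "http://www.w3.org/2002/07/owl#"
_IAO_DEFINITION = "IAO_0000115"


class OntologyImportError(g.GraphError):
    """Unknown format, duplicate tag, or cyclic subsumption."""


def concept_label(tag: str) -> str:
    return f"{tag}Ontology"


def _class_id_from_iri(iri: str) -> str:
    return iri.rstrip("/").rsplit("/", 1)[-1].rsplit("#", 1)[-1]


def _parse_obo(text: str) -> list[tuple[str, str, str, list[str], int]]:
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    concepts = []
    for node, data in graph.nodes(data=True):
        definition = data.get("def", "")
        if definition.startswith('"'):
            definition = definition[1:].split('"', 1)[0]
        parents = sorted(
            t for _s, t, k in graph.out_edges(node, keys=True) if k == "is_a"
        )
        dropped = sum(
            1 for _s, _t, k in graph.out_edges(node, keys=True) if k != "is_a"
        )
        concepts.append((node, data.get("name", ""), definition, parents, dropped))
    return concepts


def _parse_owl_xml(source: IO | str | bytes) -> list[tuple[str, str, str, list[str], int]]:
    root = etree.parse(source).getroot()
    concepts = []
    for cls in root.iter(f"{{{_OWL_NS}}}Class"):
        about = cls.get(f"{{{_RDF_NS}}}about")
        if not about:
            continue
        cid = _class_id_from_iri(about)
        label_elem = cls.find(f"{{{_RDFS_NS}}}label")
        label = label_elem.text.strip() if label_elem is not None and label_elem.text else ""
        definition = ""
        for child in cls:
            if isinstance(child.tag, str) and child.tag.endswith(_IAO_DEFINITION):
                definition = (child.text or "").strip()
        parents = []
        dropped = 0
        for sub in cls.findall(f"{{{_RDFS_NS}}}subClassOf"):
            parent_iri = sub.get(f"{{{_RDF_NS}}}resource")
            if parent_iri:
                parents.append(_class_id_from_iri(parent_iri))
            else:
                dropped += 1  # anonymous restriction, not a named superclass
        concepts.append((cid, label, definition, sorted(parents), dropped))
    if not concepts:
        raise OntologyImportError("no owl:Class elements found; unknown format?")
    return concepts


class OntologyImporter:
    def __init__(self, store: g.PropertyGraph) -> None:
        self.store = store

    def import_file(
        self, source: IO | str | bytes, ontology_tag: str, fmt: str = "auto"
    ) -> dict[str, int]:
        """Import an OBO or OWL-XML ontology under ``ontology_tag``.

        Returns a counts map: concepts, isA edges, dropped relations.
        Importing the same tag twice is rejected.
        """
        for root in self.store.nodes_by_label(g.ONTOLOGY_ROOT):
            if self.store.get(root, "TAG") == ontology_tag:
                raise OntologyImportError(f"ontology tag {ontology_tag!r} already imported")

        if fmt == "auto":
            fmt = self._sniff(source)
        if fmt == "obo":
            if hasattr(source, "read"):
                text = source.read()
                if isinstance(text, bytes):
                    text = text.decode("utf-8")
            else:
                with open(source, encoding="utf-8") as fh:
                    text = fh.read()
            concepts = _parse_obo(text)
        elif fmt == "owl":
            try:
                concepts = _parse_owl_xml(source)
            except etree.XMLSyntaxError as exc:
                raise OntologyImportError(f"cannot parse OWL-XML: {exc}") from exc
        else:
            raise OntologyImportError(f"unknown ontology format {fmt!r}")

        # cycle check on the parent lists before touching the store
        isa = nx.DiGraph()
        isa.add_nodes_from(cid for cid, *_ in concepts)
        for cid, _label, _definition, parents, _dropped in concepts:
            for parent in parents:
                if parent in isa:
                    isa.add_edge(cid, parent)
        try:
            cycle = nx.find_cycle(isa)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(s for s, _t in cycle)
            raise OntologyImportError(f"cyclic isA hierarchy: {path}")

        store = self.store
        root_node = store.add_node({g.ONTOLOGY_ROOT}, {"TAG": ontology_tag})
        label = concept_label(ontology_tag)
        nodes: dict[str, int] = {}
        dropped_total = 0
        for cid, name, definition, _parents, dropped in concepts:
            nid = store.add_node(
                {label}, {"id": cid, "LABEL": name, "DEFINITION": definition}
            )
            store.add_edge(nid, root_node, g.BELONGS_TO)
            nodes[cid] = nid
            dropped_total += dropped
        n_isa = 0
        for cid, _name, _definition, parents, _dropped in concepts:
            for parent in parents:
                if parent in nodes:
                    store.add_edge(nodes[cid], nodes[parent], g.IS_A)
                    n_isa += 1
                else:
                    dropped_total += 1
        return {"concepts": len(nodes), "isA": n_isa, "dropped_relations": dropped_total}

    @staticmethod
    def _sniff(source: IO | str | bytes) -> str:
        if hasattr(source, "read"):
            head = source.read(512)
            source.seek(0)
        else:
            with open(source, "rb") as fh:
                head = fh.read(512)
        if isinstance(head, bytes):
            head = head.decode("utf-8", "replace")
        return "owl" if head.lstrip().startswith("<") else "obo"


def _id_variants(concept_id: str) -> list[str]:
    out = [concept_id]
    if ":" in concept_id:
        out.append(concept_id.replace(":", "_"))
    if "_" in concept_id:
        out.append(concept_id.replace("_", ":", 1))
    return out


def find_concept(store: g.PropertyGraph, concept_id: str) -> int:
    """Resolve a concept id (``SBO:0000009`` / ``SBO_0000009``) or label."""
    tags = [
        store.get(r, "TAG") for r in sorted(store.nodes_by_label(g.ONTOLOGY_ROOT))
    ]
    for tag in tags:
        label = concept_label(tag)
        for variant in _id_variants(concept_id):
            hit = store.nodes_by_attribute(label, "id", variant)
            if hit:
                return min(hit)
        hit = store.nodes_by_attribute(label, "LABEL", concept_id)
        if hit:
            return min(hit)
    raise OntologyImportError(f"unknown ontology concept {concept_id!r}")


def descendants(store: g.PropertyGraph, concept_id: str) -> set[str]:
    """Transitive isA closure downward, self included (the ``*0..`` hop)."""
    node = find_concept(store, concept_id)
    closure = store.traverse([node], g.IS_A, "in", 0, None)
    return {store.get(n, "id") for n in closure}


def descendant_nodes(store: g.PropertyGraph, concept_id: str) -> set[int]:
    node = find_concept(store, concept_id)
    return store.traverse([node], g.IS_A, "in", 0, None)


def load_resource_descriptions(store: g.PropertyGraph, source: IO | str) -> int:
    """Load a tab-separated URI -> description table onto RESOURCETEXT.

    Stands in for web look-ups of protein/record descriptions (UniProt,
    InterPro, ...): each line pairs a resource URI (or canonical key)
    with free text appended to the resource's indexed description.
    """
    from .annotations import get_or_create_resource

    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    n = 0
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        uri, _sep, text = line.partition("\t")
        if not text:
            continue
        nid, _warning = get_or_create_resource(store, uri.strip())
        existing = store.get(nid, "RESOURCETEXT", "")
        store.set_attribute(nid, "RESOURCETEXT", f"{existing} {text.strip()}".strip())
        n += 1
    return n
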