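"""Shared handling of RDF/MIRIAM annotations for the XML importers.

An annotated model element gets one ANNOTATION container node; every
qualified reference inside it becomes a qualifier-typed edge
(``is``, ``isVersionOf``, ``hasPart``, ``isDescribedBy``, ...) from the
container to a deduplicated RESOURCE node.  The reverse BELONGS_TO edges
(annotation -> element, resource -> annotation) keep the store traversable
upwards from any resource to the documents using it.
"""

from __future__ import annotations

from lxml import etree

from . import graph as g
from .uris import local_part, normalize_uri

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"

_KNOWN_QUALIFIERS = {
    "is", "isVersionOf", "hasPart", "isPartOf", "hasVersion", "isHomologTo",
    "isDescribedBy", "isEncodedBy", "encodes", "occursIn", "hasProperty",
    "isPropertyOf", "hasTaxon", "isDerivedFrom", "isInstanceOf", "hasInstance",
}


def extract_qualified_resources(
    rdf_root: etree._Element,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pull ``(qualifier, uri)`` pairs out of an RDF annotation block.

    Returns the pairs plus warnings for qualifiers outside the MIRIAM
    vocabulary (they are kept, typed by their local name).
    """
    pairs: list[tuple[str, str]] = []
    warnings: list[str] = []
    for elem in rdf_root.iter():
        qname = etree.QName(elem)
        if qname.namespace not in (BQBIOL_NS, BQMODEL_NS):
            continue
        qualifier = qname.localname
        if qualifier not in _KNOWN_QUALIFIERS:
            warnings.append(f"unknown annotation qualifier {qualifier!r}; kept verbatim")
        for li in elem.iter(f"{{{RDF_NS}}}li"):
            uri = li.get(f"{{{RDF_NS}}}resource")
            if uri:
                pairs.append((qualifier, uri))
    return pairs, warnings


def get_or_create_resource(store: g.PropertyGraph, uri: str) -> tuple[int, str | None]:
    """Resolve a URI to its (deduplicated) RESOURCE node."""
    key, warning = normalize_uri(uri)
    existing = store.nodes_by_attribute(g.RESOURCE, "KEY", key.key)
    if existing:
        return min(existing), warning
    labels = {g.RESOURCE}
    if key.collection == "pubmed":
        labels.add(g.PUBLICATION)
    nid = store.add_node(
        labels,
        {"URI": uri, "KEY": key.key, "RESOURCETEXT": local_part(uri)},
    )
    return nid, warning


def attach_annotation(
    store: g.PropertyGraph,
    element: int,
    qualified_uris: list[tuple[str, str]],
) -> int | None:
    """Create the annotation container for one element.

    Edges created: element -hasAnnotation-> annotation,
    annotation -BELONGS_TO-> element, annotation -<qualifier>-> resource,
    resource -BELONGS_TO-> annotation.
    """
    if not qualified_uris:
        return None
    ann = store.add_node({g.ANNOTATION}, {})
    store.add_edge(element, ann, g.HAS_ANNOTATION)
    store.add_edge(ann, element, g.BELONGS_TO)
    for qualifier, uri in qualified_uris:
        res, _warning = get_or_create_resource(store, uri)
        store.add_edge(ann, res, qualifier)
        store.add_edge(res, ann, g.BELONGS_TO)
    return ann
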