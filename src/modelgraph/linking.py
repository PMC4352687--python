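"""Materialize the four cross-domain link types.

(a) annotation -> ontology concept: a RESOURCE whose URI names an
    ontology (e.g. contains "SBO") is paired with the concept whose id
    shares its last seven characters — bio-ontology accessions are
    zero-padded to seven digits, so the suffix is the accession.
(b) SED-ML model reference -> stored model, by resolving MODELSOURCE.
(c) data-generator variable -> observed model entity, by resolving the
    variable's XPath target inside the referenced model; species touched
    by pre-processing changes are flagged IS_CHANGED.
(d) implicit cross-format entity links: for two models of different
    formats sharing a reference publication, similarly named entities
    are joined by IS_SIMILAR_TO edges carrying a confidence score.

Links (a)-(c) are explicit (confidence 1.0); (d) is inferred.  Every
linker is idempotent: existing edges are never duplicated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import graph as g
from .ontology import concept_label
from .similarity import name_similarity

DEFAULT_SUFFIX_LENGTH = 7
DEFAULT_THRESHOLD = 0.7
DEFAULT_WEIGHTS = (0.7, 0.3)

_ENTITY_LABELS_SBML = (g.SBML_SPECIES, g.SBML_COMPARTMENT, g.SBML_PARAMETER)
_ENTITY_LABELS_CELLML = (g.CELLML_COMPONENT, g.CELLML_VARIABLE)

# XPath subset: any [@id='X'] / [@name='X'] predicate, single or double quotes
_PREDICATE_RE = re.compile(r"\[@(id|name)=(['\"])(.*?)\2\]")


class LinkerError(g.GraphError):
    """Ambiguous or invalid linking request."""


@dataclass
class LinkRecord:
    """One materialized link, with provenance."""

    link_type: str  # a | b | c | d
    source: int
    target: int
    edge_type: str
    confidence: float
    evidence: str


# ----------------------------------------------------------------------
# (a) annotations -> ontology concepts
# ----------------------------------------------------------------------
def link_annotations_to_ontology(
    store: g.PropertyGraph,
    ontology_tag: str,
    suffix_length: int = DEFAULT_SUFFIX_LENGTH,
) -> int:
    """Create IS_ONTOLOGY_ENTRY edges resource -> concept; returns the count.

    A resource participates if its URI contains the ontology tag; it is
    matched to the concept whose id ends in the same ``suffix_length``
    characters.  A resource matching two concepts is an error (never
    silently picked).  Newly linked resources get the concept's label
    and definition appended to their indexed description text.
    """
    concepts = store.nodes_by_label(concept_label(ontology_tag))
    if not concepts:
        raise LinkerError(f"no ontology imported under tag {ontology_tag!r}")
    by_suffix: dict[str, list[int]] = {}
    for cid in concepts:
        concept_id = str(store.get(cid, "id", ""))
        if len(concept_id) >= suffix_length:
            by_suffix.setdefault(concept_id[-suffix_length:], []).append(cid)
    created = 0
    for res in sorted(store.nodes_by_label(g.RESOURCE)):
        uri = str(store.get(res, "URI", ""))
        if ontology_tag not in uri or len(uri) < suffix_length:
            continue
        candidates = by_suffix.get(uri[-suffix_length:], [])
        if not candidates:
            continue
        if len(candidates) > 1:
            ids = ", ".join(sorted(str(store.get(c, "id")) for c in candidates))
            raise LinkerError(f"resource {uri!r} matches multiple concepts: {ids}")
        concept = candidates[0]
        if store.has_edge(res, concept, g.IS_ONTOLOGY_ENTRY):
            continue
        store.add_edge(res, concept, g.IS_ONTOLOGY_ENTRY)
        extra = f"{store.get(concept, 'LABEL', '')} {store.get(concept, 'DEFINITION', '')}".strip()
        if extra:
            text = store.get(res, "RESOURCETEXT", "")
            store.set_attribute(res, "RESOURCETEXT", f"{text} {extra}".strip())
        created += 1
    return created


# ----------------------------------------------------------------------
# (b) SED-ML model references -> stored models
# ----------------------------------------------------------------------
def _model_of_document(store: g.PropertyGraph, doc: int) -> int | None:
    for m in sorted(store.neighbors(doc, g.HAS_MODEL, "out")):
        if store.labels(m) & {g.SBML_MODEL, g.CELLML_MODEL}:
            return m
    return None


def resolve_model_source(store: g.PropertyGraph, source: str) -> tuple[int | None, str]:
    """Resolve a MODELSOURCE string to a stored model node.

    Order: exact FILENAME match on a document, exact model ID attribute,
    then document basename.  Returns ``(node or None, note)``.
    """
    docs = store.nodes_by_attribute(g.DOCUMENT, "FILENAME", source)
    models = sorted(m for m in (_model_of_document(store, d) for d in docs) if m is not None)
    how = "filename match"
    if not models:
        models = sorted(
            store.nodes_by_attribute(g.SBML_MODEL, "ID", source)
            | store.nodes_by_attribute(g.CELLML_MODEL, "ID", source)
        )
        how = "model id match"
    if not models:
        base = source.rstrip("/").rsplit("/", 1)[-1]
        hits = [
            d
            for d in store.nodes_by_label(g.DOCUMENT)
            if str(store.get(d, "FILENAME", "")).rsplit("/", 1)[-1] == base
        ]
        models = sorted(m for m in (_model_of_document(store, d) for d in hits) if m is not None)
        how = "basename match"
    if not models:
        return None, "unresolved"
    if len(models) > 1:
        return models[0], f"ambiguous {how} ({len(models)} candidates; first kept)"
    return models[0], how


def link_sedml_to_models(store: g.PropertyGraph) -> tuple[list[LinkRecord], list[str]]:
    records: list[LinkRecord] = []
    unresolved: list[str] = []
    for ref in sorted(store.nodes_by_label(g.SEDML_MODELREFERENCE)):
        source = str(store.get(ref, "MODELSOURCE", ""))
        model, note = resolve_model_source(store, source)
        if model is None:
            unresolved.append(source)
            continue
        if store.has_edge(ref, model, g.REFERENCES_SIMULATION_MODEL):
            continue
        store.add_edge(ref, model, g.REFERENCES_SIMULATION_MODEL)
        records.append(
            LinkRecord("b", ref, model, g.REFERENCES_SIMULATION_MODEL, 1.0, note)
        )
    return records, unresolved


# ----------------------------------------------------------------------
# (c) data-generator variables -> model entities
# ----------------------------------------------------------------------
def _xpath_names(target: str) -> list[tuple[str, str]]:
    return [(m.group(1), m.group(3)) for m in _PREDICATE_RE.finditer(target)]


def _model_entities(store: g.PropertyGraph, model: int) -> list[int]:
    # entities sit one or two BELONGS_TO hops below the model node
    nodes = store.traverse([model], g.BELONGS_TO, "in", 1, 2)
    keep = set(_ENTITY_LABELS_SBML + _ENTITY_LABELS_CELLML) | {
        g.SBML_REACTION, g.SBML_FUNCTION, g.SBML_ELEMENT
    }
    return sorted(n for n in nodes if store.labels(n) & keep)


def _resolve_target(store: g.PropertyGraph, model: int, target: str) -> int | None:
    names = _xpath_names(target)
    if not names:
        return None
    wanted = names[-1][1]
    entities = _model_entities(store, model)
    for attr in ("ID", "NAME"):
        hits = [e for e in entities if store.get(e, attr) == wanted]
        if len(names) >= 2 and attr == "NAME" and len(hits) > 1:
            # CellML: disambiguate variable by its component name
            comp = names[-2][1]
            hits = [
                e
                for e in hits
                if any(
                    store.get(c, "NAME") == comp
                    for c in store.neighbors(e, g.BELONGS_TO, "out")
                )
            ]
        if hits:
            return min(hits)
    return None


def _reference_targets(store: g.PropertyGraph, ref: int) -> list[int]:
    return sorted(store.neighbors(ref, g.REFERENCES_SIMULATION_MODEL, "out"))


def link_datagenerators_to_entities(
    store: g.PropertyGraph,
) -> tuple[list[LinkRecord], list[str]]:
    """Create OBSERVES edges variable -> entity; flag changed species.

    Requires :func:`link_sedml_to_models` to have run, so that model
    references already point at stored models.
    """
    records: list[LinkRecord] = []
    unresolved: list[str] = []
    ref_by_doc_id: dict[tuple[int, str], int] = {}
    for ref in store.nodes_by_label(g.SEDML_MODELREFERENCE):
        anchors = store.neighbors(ref, g.BELONGS_TO, "out")
        for anchor in anchors:
            ref_by_doc_id[(anchor, str(store.get(ref, "ID", "")))] = ref

    for var in sorted(store.nodes_by_label(g.SEDML_VARIABLE)):
        target = str(store.get(var, "TARGET", ""))
        if not target or target.startswith("urn:"):  # symbols like time
            continue
        anchor_set = store.traverse([var], g.BELONGS_TO, "out", 2, 2)
        anchors = [a for a in anchor_set if g.SEDML_DOCUMENT in store.labels(a)]
        ref = None
        if anchors:
            ref = ref_by_doc_id.get((anchors[0], str(store.get(var, "MODELREF", ""))))
        if ref is None:
            unresolved.append(target)
            continue
        hit = None
        for model in _reference_targets(store, ref):
            hit = _resolve_target(store, model, target)
            if hit is not None:
                break
        if hit is None:
            unresolved.append(target)
            continue
        if not store.has_edge(var, hit, g.OBSERVES):
            store.add_edge(var, hit, g.OBSERVES)
            records.append(LinkRecord("c", var, hit, g.OBSERVES, 1.0, "xpath target"))

    for change in sorted(store.nodes_by_label(g.SEDML_CHANGE)):
        target = str(store.get(change, "TARGET", ""))
        refs = [
            r
            for r in store.neighbors(change, g.BELONGS_TO, "out")
            if g.SEDML_MODELREFERENCE in store.labels(r)
        ]
        for ref in refs:
            for model in _reference_targets(store, ref):
                hit = _resolve_target(store, model, target)
                if hit is not None:
                    store.set_attribute(hit, "IS_CHANGED", True)
    return records, unresolved


# ----------------------------------------------------------------------
# (d) implicit cross-format entity links
# ----------------------------------------------------------------------
def _models_sharing_publication(store: g.PropertyGraph) -> list[tuple[int, int, int]]:
    """(publication, sbml model, cellml model) triples."""
    triples = []
    for pub in sorted(store.nodes_by_label(g.PUBLICATION)):
        sbml, cellml = set(), set()
        for ann in store.neighbors(pub, g.BELONGS_TO, "out"):
            for elem in store.neighbors(ann, g.BELONGS_TO, "out"):
                candidates = {elem} | store.neighbors(elem, g.BELONGS_TO, "out")
                for c in candidates:
                    labels = store.labels(c)
                    if g.SBML_MODEL in labels:
                        sbml.add(c)
                    elif g.CELLML_MODEL in labels:
                        cellml.add(c)
        for m1 in sorted(sbml):
            for m2 in sorted(cellml):
                triples.append((pub, m1, m2))
    return triples


def _entities_with_names(
    store: g.PropertyGraph, model: int, labels: tuple[str, ...]
) -> list[int]:
    out = []
    for n in store.traverse([model], g.BELONGS_TO, "in", 1, 2):
        if store.labels(n) & set(labels) and store.get(n, "NAME"):
            out.append(n)
    return sorted(out)


def _annotation_keys(store: g.PropertyGraph, entity: int) -> set[str]:
    keys = set()
    for ann in store.neighbors(entity, g.HAS_ANNOTATION, "out"):
        for res in store.neighbors(ann, g.WILDCARD, "out"):
            if g.RESOURCE in store.labels(res):
                keys.add(str(store.get(res, "KEY", "")))
    return keys


def infer_cross_format_links(
    store: g.PropertyGraph,
    threshold: float = DEFAULT_THRESHOLD,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> list[LinkRecord]:
    """Infer IS_SIMILAR_TO edges between entities of cross-format twins.

    Only models that share a reference publication participate (the
    gating condition).  Candidate pairs are the cross product of named
    SBML entities (species, compartments, parameters) and CellML
    entities (components, variables); a pair scores

        score = w_name * sim(nameA, nameB) + w_ann * [shared annotation]

    and survives if score >= threshold.  Each entity keeps only its
    best-scoring counterpart (ties broken lexicographically by the
    counterpart's name); the symmetric edge is stored once.
    """
    if not 0.0 <= threshold <= 1.0:
        raise LinkerError("threshold must lie in [0, 1]")
    w_name, w_ann = weights
    records: list[LinkRecord] = []
    seen_pairs: set[tuple[int, int]] = set()
    for _pub, sbml_model, cellml_model in _models_sharing_publication(store):
        left = _entities_with_names(store, sbml_model, _ENTITY_LABELS_SBML)
        right = _entities_with_names(store, cellml_model, _ENTITY_LABELS_CELLML)
        if not left or not right:
            continue
        left_keys = {e: _annotation_keys(store, e) for e in left}
        right_keys = {e: _annotation_keys(store, e) for e in right}
        scored: dict[tuple[int, int], tuple[float, float, bool]] = {}
        for a in left:
            name_a = str(store.get(a, "NAME"))
            for b in right:
                name_b = str(store.get(b, "NAME"))
                sim = name_similarity(name_a, name_b)
                shared = bool(left_keys[a] & right_keys[b])
                score = w_name * sim + w_ann * (1.0 if shared else 0.0)
                if score >= threshold:
                    scored[(a, b)] = (score, sim, shared)

        def best_of(entity: int, side: int) -> tuple[int, int] | None:
            pairs = [p for p in scored if p[side] == entity]
            if not pairs:
                return None
            other = 1 - side
            return min(
                pairs,
                key=lambda p: (-scored[p][0], str(store.get(p[other], "NAME"))),
            )

        keep: set[tuple[int, int]] = set()
        for a in left:
            p = best_of(a, 0)
            if p:
                keep.add(p)
        for b in right:
            p = best_of(b, 1)
            if p:
                keep.add(p)

        for a, b in sorted(keep):
            if (a, b) in seen_pairs or store.has_edge(a, b, g.IS_SIMILAR_TO):
                continue
            seen_pairs.add((a, b))
            score, sim, shared = scored[(a, b)]
            bits = ["shared publication"]
            bits.append("exact name" if sim == 1.0 else f"levenshtein {sim:.2f}")
            if shared:
                bits.append("shared annotation")
            store.add_edge(a, b, g.IS_SIMILAR_TO, {"confidence": score})
            records.append(
                LinkRecord("d", a, b, g.IS_SIMILAR_TO, score, " + ".join(bits))
            )
    return records

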