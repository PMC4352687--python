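"""SBML importer: maps a reaction-network model onto the graph schema.

A document root node anchors the import; the model node hangs off it via
``hasModel`` and fans out to species, reactions, compartments, global
parameters and function definitions.  Reaction participation is encoded
as species -> reaction edges typed IS_REACTANT / IS_PRODUCT /
IS_MODIFIER, and species sit in their compartment via ``isContainedIn``.
MIRIAM annotations become annotation-container + resource nodes.

Supported: SBML Level 2 (any version) and Level 3 core.  Unit
declarations are skipped (reported); package extensions (comp, fbc, ...)
are ignored with a warning.  Kinetic-law math is kept verbatim as a text
attribute — no printed use case needs its structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from lxml import etree

from . import graph as g
from .annotations import RDF_NS, attach_annotation, extract_qualified_resources

_L2_PREFIX = "http://www.sbml.org/sbml/level2"
_L3_PREFIX = "http://www.sbml.org/sbml/level3"


class SbmlImportError(g.GraphError):
    """Raised when a document cannot be mapped (parse error, no model)."""


@dataclass
class SbmlImportReport:
    """What one SBML import created."""

    document_node: int
    counts: dict[str, int] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _local(elem: etree._Element) -> str:
    return etree.QName(elem).localname


def _sbml_children(parent: etree._Element, container: str, child: str) -> list:
    ns = etree.QName(parent).namespace
    box = parent.find(f"{{{ns}}}{container}")
    if box is None:
        return []
    return box.findall(f"{{{ns}}}{child}")


def _annotation_pairs(elem: etree._Element) -> tuple[list[tuple[str, str]], list[str]]:
    ns = etree.QName(elem).namespace
    ann = elem.find(f"{{{ns}}}annotation")
    if ann is None:
        return [], []
    rdf = ann.find(f"{{{RDF_NS}}}RDF")
    if rdf is None:
        return [], []
    return extract_qualified_resources(rdf)


class SbmlImporter:
    """Writes SBML documents into a :class:`~modelgraph.graph.PropertyGraph`."""

    def __init__(self, store: g.PropertyGraph) -> None:
        self.store = store

    def import_file(self, source: IO | str | bytes, filename: str) -> SbmlImportReport:
        try:
            root = etree.parse(source).getroot()
        except (etree.XMLSyntaxError, OSError) as exc:
            raise SbmlImportError(f"{filename}: cannot parse XML: {exc}") from exc
        ns = etree.QName(root).namespace or ""
        if _local(root) != "sbml" or not (
            ns.startswith(_L2_PREFIX) or ns.startswith(_L3_PREFIX)
        ):
            raise SbmlImportError(f"{filename}: not an SBML Level 2/3 document")

        store = self.store
        counts: dict[str, int] = {}
        report = SbmlImportReport(document_node=-1, counts=counts)

        def bump(label: str) -> None:
            counts[label] = counts.get(label, 0) + 1

        extra_ns = {
            etree.QName(e).namespace
            for e in root.iter()
            if isinstance(e.tag, str)
        } - {ns, RDF_NS}
        for pkg_ns in sorted(x for x in extra_ns if x and "sbml.org" in x and "/core" not in x):
            report.warnings.append(f"SBML package namespace ignored: {pkg_ns}")

        model_elem = root.find(f"{{{ns}}}model")
        if model_elem is None:
            raise SbmlImportError(f"{filename}: document has no model element")

        doc = store.add_node({g.DOCUMENT}, {"FILENAME": filename})
        report.document_node = doc
        model = store.add_node(
            {g.SBML_MODEL},
            {
                "ID": model_elem.get("id", ""),
                "NAME": model_elem.get("name", model_elem.get("id", "")),
            },
        )
        bump(g.SBML_MODEL)
        store.add_edge(doc, model, g.HAS_MODEL)
        store.add_edge(model, doc, g.BELONGS_TO)
        self._annotate(model_elem, model, report)

        if _sbml_children(model_elem, "listOfUnitDefinitions", "unitDefinition"):
            report.skipped.append("unitDefinition")

        compartments: dict[str, int] = {}
        for elem in _sbml_children(model_elem, "listOfCompartments", "compartment"):
            nid = self._entity(elem, g.SBML_COMPARTMENT, g.HAS_COMPARTMENT, model, report)
            bump(g.SBML_COMPARTMENT)
            compartments[elem.get("id", "")] = nid

        species_nodes: dict[str, int] = {}
        for elem in _sbml_children(model_elem, "listOfSpecies", "species"):
            nid = self._entity(elem, g.SBML_SPECIES, g.HAS_SPECIES, model, report)
            bump(g.SBML_SPECIES)
            species_nodes[elem.get("id", "")] = nid
            comp_id = elem.get("compartment")
            if comp_id:
                if comp_id in compartments:
                    store.add_edge(nid, compartments[comp_id], g.IS_CONTAINED_IN)
                else:
                    report.warnings.append(
                        f"species {elem.get('id')!r} names unknown compartment {comp_id!r}"
                    )

        for elem in _sbml_children(model_elem, "listOfParameters", "parameter"):
            self._entity(elem, g.SBML_PARAMETER, g.HAS_PARAMETER, model, report)
            bump(g.SBML_PARAMETER)

        for elem in _sbml_children(model_elem, "listOfFunctionDefinitions", "functionDefinition"):
            self._entity(elem, g.SBML_FUNCTION, g.HAS_FUNCTION, model, report)
            bump(g.SBML_FUNCTION)

        for elem in _sbml_children(model_elem, "listOfReactions", "reaction"):
            rid = self._entity(elem, g.SBML_REACTION, g.HAS_REACTION, model, report)
            bump(g.SBML_REACTION)
            self._reaction_details(elem, rid, species_nodes, report, bump)

        # events and rules map to generic element nodes
        for container, child in (
            ("listOfEvents", "event"),
            ("listOfRules", "assignmentRule"),
            ("listOfRules", "rateRule"),
            ("listOfRules", "algebraicRule"),
        ):
            for elem in _sbml_children(model_elem, container, child):
                nid = store.add_node(
                    {g.SBML_ELEMENT},
                    {"ID": elem.get("id", ""), "KIND": _local(elem)},
                )
                bump(g.SBML_ELEMENT)
                store.add_edge(nid, model, g.BELONGS_TO)
                self._annotate(elem, nid, report)
        return report

    # ------------------------------------------------------------------
    def _entity(
        self,
        elem: etree._Element,
        label: str,
        down_edge: str,
        model: int,
        report: SbmlImportReport,
    ) -> int:
        store = self.store
        attrs = {"ID": elem.get("id", ""), "NAME": elem.get("name", elem.get("id", ""))}
        nid = store.add_node({label}, attrs)
        store.add_edge(model, nid, down_edge)
        store.add_edge(nid, model, g.BELONGS_TO)
        self._annotate(elem, nid, report)
        return nid

    def _annotate(self, elem: etree._Element, node: int, report: SbmlImportReport) -> None:
        pairs, warnings = _annotation_pairs(elem)
        report.warnings.extend(warnings)
        ann = attach_annotation(self.store, node, pairs)
        if ann is not None:
            report.counts[g.ANNOTATION] = report.counts.get(g.ANNOTATION, 0) + 1

    def _reaction_details(
        self,
        elem: etree._Element,
        reaction: int,
        species_nodes: dict[str, int],
        report: SbmlImportReport,
        bump,
    ) -> None:
        store = self.store
        ns = etree.QName(elem).namespace
        role_map = {
            "listOfReactants": g.IS_REACTANT,
            "listOfProducts": g.IS_PRODUCT,
            "listOfModifiers": g.IS_MODIFIER,
        }
        for container, edge_type in role_map.items():
            box = elem.find(f"{{{ns}}}{container}")
            if box is None:
                continue
            for ref in box:
                if _local(ref) not in ("speciesReference", "modifierSpeciesReference"):
                    continue
                sid = ref.get("species", "")
                if sid not in species_nodes:
                    report.warnings.append(
                        f"reaction {elem.get('id')!r} references unknown species {sid!r}"
                    )
                    continue
                snode = species_nodes[sid]
                stoich = float(ref.get("stoichiometry", "1"))
                if store.has_edge(snode, reaction, edge_type):
                    # repeated role collapses onto one edge, stoichiometry summed
                    attrs = store.edge_attributes(snode, reaction, edge_type)
                    attrs["stoichiometry"] = attrs.get("stoichiometry", 0.0) + stoich
                else:
                    store.add_edge(snode, reaction, edge_type, {"stoichiometry": stoich})
        law = elem.find(f"{{{ns}}}kineticLaw")
        if law is not None:
            math = law.find("{http://www.w3.org/1998/Math/MathML}math")
            if math is not None:
                store.set_attribute(
                    reaction, "MATH", etree.tostring(math, encoding="unicode")
                )
            for box_name in ("listOfParameters", "listOfLocalParameters"):
                box = law.find(f"{{{ns}}}{box_name}")
                if box is None:
                    continue
                for par in box:
                    nid = store.add_node(
                        {g.SBML_PARAMETER},
                        {"ID": par.get("id", ""), "NAME": par.get("name", par.get("id", ""))},
                    )
                    bump(g.SBML_PARAMETER)
                    store.add_edge(nid, reaction, g.BELONGS_TO)
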