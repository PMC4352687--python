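"""CellML importer: components, variables and variable mappings.

CellML encodes a model as components holding variables; connections map
a variable in one component onto a variable in another.  The graph
mirrors that: model -> component -> variable down-edges, BELONGS_TO
up-edges, and MAPPED_TO edges between connected variable nodes
(stored once per ``map_variables`` entry, first-listed component to
second; matching treats them as undirected since connections are
symmetric).  RDF metadata, if present, uses the same annotation/resource
scheme as SBML — including the shared publication node.

CellML 1.0 and 1.1 are accepted; later versions are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from lxml import etree

from . import graph as g
from .annotations import RDF_NS, attach_annotation, extract_qualified_resources

_CELLML_NS = {
    "http://www.cellml.org/cellml/1.0#",
    "http://www.cellml.org/cellml/1.1#",
}
_CMETA_NS = "http://www.cellml.org/metadata/1.0#"


class CellmlImportError(g.GraphError):
    """Unparseable or unsupported CellML document."""


@dataclass
class CellmlImportReport:
    document_node: int
    counts: dict[str, int] = field(default_factory=dict)
    unresolved_connections: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class CellmlImporter:
    def __init__(self, store: g.PropertyGraph) -> None:
        self.store = store

    def import_file(self, source: IO | str | bytes, filename: str) -> CellmlImportReport:
        try:
            root = etree.parse(source).getroot()
        except (etree.XMLSyntaxError, OSError) as exc:
            raise CellmlImportError(f"{filename}: cannot parse XML: {exc}") from exc
        ns = etree.QName(root).namespace or ""
        if etree.QName(root).localname != "model":
            raise CellmlImportError(f"{filename}: root element is not a CellML model")
        if ns not in _CELLML_NS:
            raise CellmlImportError(
                f"{filename}: unsupported CellML namespace {ns!r} (only 1.0/1.1)"
            )

        store = self.store
        counts: dict[str, int] = {}
        report = CellmlImportReport(document_node=-1, counts=counts)

        doc = store.add_node({g.DOCUMENT}, {"FILENAME": filename})
        report.document_node = doc
        model = store.add_node(
            {g.CELLML_MODEL}, {"NAME": root.get("name", ""), "ID": root.get("name", "")}
        )
        counts[g.CELLML_MODEL] = 1
        store.add_edge(doc, model, g.HAS_MODEL)
        store.add_edge(model, doc, g.BELONGS_TO)

        # element lookup for metadata ids and connections
        by_cmeta: dict[str, int] = {}
        cmeta = root.get(f"{{{_CMETA_NS}}}id")
        if cmeta:
            by_cmeta[cmeta] = model

        variables: dict[tuple[str, str], int] = {}
        for comp in root.findall(f"{{{ns}}}component"):
            cname = comp.get("name", "")
            cnode = store.add_node({g.CELLML_COMPONENT}, {"NAME": cname, "ID": cname})
            counts[g.CELLML_COMPONENT] = counts.get(g.CELLML_COMPONENT, 0) + 1
            store.add_edge(model, cnode, g.HAS_COMPONENT)
            store.add_edge(cnode, model, g.BELONGS_TO)
            cm = comp.get(f"{{{_CMETA_NS}}}id")
            if cm:
                by_cmeta[cm] = cnode
            math = comp.find("{http://www.w3.org/1998/Math/MathML}math")
            if math is not None:
                store.set_attribute(cnode, "MATH", etree.tostring(math, encoding="unicode"))
            for var in comp.findall(f"{{{ns}}}variable"):
                vname = var.get("name", "")
                vnode = store.add_node(
                    {g.CELLML_VARIABLE}, {"NAME": vname, "ID": vname}
                )
                counts[g.CELLML_VARIABLE] = counts.get(g.CELLML_VARIABLE, 0) + 1
                store.add_edge(cnode, vnode, g.HAS_VARIABLE)
                store.add_edge(vnode, cnode, g.BELONGS_TO)
                variables[(cname, vname)] = vnode
                vm = var.get(f"{{{_CMETA_NS}}}id")
                if vm:
                    by_cmeta[vm] = vnode

        for conn in root.findall(f"{{{ns}}}connection"):
            mc = conn.find(f"{{{ns}}}map_components")
            if mc is None:
                continue
            c1, c2 = mc.get("component_1", ""), mc.get("component_2", "")
            for mv in conn.findall(f"{{{ns}}}map_variables"):
                v1, v2 = mv.get("variable_1", ""), mv.get("variable_2", "")
                n1 = variables.get((c1, v1))
                n2 = variables.get((c2, v2))
                if n1 is None:
                    report.unresolved_connections.append((c1, v1))
                    continue
                if n2 is None:
                    report.unresolved_connections.append((c2, v2))
                    continue
                store.add_edge(n1, n2, g.MAPPED_TO)

        self._import_rdf(root, model, by_cmeta, report)
        return report

    def _import_rdf(
        self,
        root: etree._Element,
        model: int,
        by_cmeta: dict[str, int],
        report: CellmlImportReport,
    ) -> None:
        for rdf in root.iter(f"{{{RDF_NS}}}RDF"):
            for desc in rdf.findall(f"{{{RDF_NS}}}Description"):
                about = desc.get(f"{{{RDF_NS}}}about", "")
                if about in ("", "#"):
                    target = model
                elif about.startswith("#") and about[1:] in by_cmeta:
                    target = by_cmeta[about[1:]]
                else:
                    report.warnings.append(f"RDF description about unknown id {about!r}")
                    continue
                pairs, warnings = extract_qualified_resources(desc)
                report.warnings.extend(warnings)
                if attach_annotation(self.store, target, pairs) is not None:
                    report.counts[g.ANNOTATION] = report.counts.get(g.ANNOTATION, 0) + 1
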