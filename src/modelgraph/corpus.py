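"""Convenience loading of whole file corpora into one store.

Dispatches on filename extension: ``.sbml.xml``/``.xml`` -> SBML,
``.cellml`` -> CellML, ``.sedml`` -> SED-ML, ``.obo``/``.owl`` ->
ontology (tagged by the first filename token, upper-cased), ``.tsv`` ->
resource-description table.  Used by the test suite, the acceptance
script and as a library shortcut; the CLI has its own sniffing on file
content.
"""

from __future__ import annotations

import io

from . import graph as g
from .cellml import CellmlImporter
from .linking import (
    infer_cross_format_links,
    link_annotations_to_ontology,
    link_datagenerators_to_entities,
    link_sedml_to_models,
)
from .ontology import OntologyImporter, load_resource_descriptions
from .sbml import SbmlImporter
from .sedml import SedmlImporter


def import_corpus(store: g.PropertyGraph, files: dict[str, str]) -> dict[str, object]:
    """Import an in-memory ``{filename: content}`` corpus; returns reports."""
    reports: dict[str, object] = {}
    for name in sorted(files):
        content = files[name]
        src = io.BytesIO(content.encode("utf-8"))
        if name.endswith((".sbml.xml", ".xml")):
            reports[name] = SbmlImporter(store).import_file(src, name)
        elif name.endswith(".cellml"):
            reports[name] = CellmlImporter(store).import_file(src, name)
        elif name.endswith(".sedml"):
            reports[name] = SedmlImporter(store).import_file(src, name)
        elif name.endswith((".obo", ".owl")):
            tag = name.split(".")[0].upper()
            reports[name] = OntologyImporter(store).import_file(src, tag)
        elif name.endswith(".tsv"):
            reports[name] = load_resource_descriptions(store, io.StringIO(content))
        else:
            raise g.ValidationError(f"cannot infer format of {name!r}")
    return reports


def link_all(
    store: g.PropertyGraph,
    threshold: float = 0.7,
    suffix_length: int = 7,
) -> dict[str, int]:
    """Run all four linkers over every imported ontology; returns counts."""
    counts = {"a": 0, "b": 0, "c": 0, "d": 0}
    for root in sorted(store.nodes_by_label(g.ONTOLOGY_ROOT)):
        tag = str(store.get(root, "TAG"))
        counts["a"] += link_annotations_to_ontology(store, tag, suffix_length)
    counts["b"] = len(link_sedml_to_models(store)[0])
    counts["c"] = len(link_datagenerators_to_entities(store)[0])
    counts["d"] = len(infer_cross_format_links(store, threshold))
    return counts
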