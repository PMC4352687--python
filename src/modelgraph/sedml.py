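"""SED-ML importer: simulation setups, model references and observations.

A SED-ML file describes which models to simulate, with which algorithm
(a KiSAO term), and which variables to observe.  The import anchors the
experiment on a SEDML node under the document root, creates one
SEDML_MODELREFERENCE per listed model (MODELSOURCE kept verbatim), one
SEDML_SIMULATION per simulation (SIMKISAO from the algorithm), SIMULATES
edges simulation -> model reference derived from the tasks, and one
SEDML_VARIABLE node per data-generator variable with its XPath TARGET
kept verbatim for the linker.  Pre-processing changes are recorded as
SEDML_CHANGE nodes on the model reference.

BELONGS_TO depths are fixed by the anchor: model references and
simulations sit exactly two upward hops from the document, variables
three.  repeatedTask entries are flattened onto their leaf tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from lxml import etree

from . import graph as g

_SEDML_PREFIX = "http://sed-ml.org/"

HAS_SEDML = "hasSedml"
HAS_MODELREFERENCE = "hasModelReference"
HAS_SIMULATION = "hasSimulation"
HAS_DATAGENERATOR = "hasDataGenerator"
HAS_CHANGE = "hasChange"


class SedmlImportError(g.GraphError):
    """Unparseable SED-ML or dangling task references."""


@dataclass
class SedmlImportReport:
    document_node: int
    model_references: list[tuple[int, str]] = field(default_factory=list)
    simulations: list[tuple[int, str]] = field(default_factory=list)
    datagenerators: int = 0
    changes: int = 0
    warnings: list[str] = field(default_factory=list)


class SedmlImporter:
    def __init__(self, store: g.PropertyGraph) -> None:
        self.store = store

    def import_file(self, source: IO | str | bytes, filename: str) -> SedmlImportReport:
        try:
            root = etree.parse(source).getroot()
        except (etree.XMLSyntaxError, OSError) as exc:
            raise SedmlImportError(f"{filename}: cannot parse XML: {exc}") from exc
        ns = etree.QName(root).namespace or ""
        if etree.QName(root).localname != "sedML" or not ns.startswith(_SEDML_PREFIX):
            raise SedmlImportError(f"{filename}: not a SED-ML Level 1 document")

        store = self.store
        doc = store.add_node({g.DOCUMENT}, {"FILENAME": filename})
        anchor = store.add_node({g.SEDML_DOCUMENT}, {"FILENAME": filename})
        store.add_edge(doc, anchor, HAS_SEDML)
        store.add_edge(anchor, doc, g.BELONGS_TO)
        report = SedmlImportReport(document_node=doc)

        def children(parent, container, *names):
            box = parent.find(f"{{{ns}}}{container}")
            if box is None:
                return []
            return [e for e in box if etree.QName(e).localname in names]

        model_refs: dict[str, int] = {}
        for elem in children(root, "listOfModels", "model"):
            mid = elem.get("id", "")
            node = store.add_node(
                {g.SEDML_MODELREFERENCE},
                {
                    "ID": mid,
                    "MODELSOURCE": elem.get("source", ""),
                    "LANGUAGE": elem.get("language", ""),
                },
            )
            store.add_edge(anchor, node, HAS_MODELREFERENCE)
            store.add_edge(node, anchor, g.BELONGS_TO)
            model_refs[mid] = node
            report.model_references.append((node, elem.get("source", "")))
            for changes_box in ("listOfChanges",):
                box = elem.find(f"{{{ns}}}{changes_box}")
                if box is None:
                    continue
                for change in box:
                    cnode = store.add_node(
                        {g.SEDML_CHANGE},
                        {
                            "TARGET": change.get("target", ""),
                            "KIND": etree.QName(change).localname,
                        },
                    )
                    store.add_edge(node, cnode, HAS_CHANGE)
                    store.add_edge(cnode, node, g.BELONGS_TO)
                    report.changes += 1

        simulations: dict[str, int] = {}
        for elem in children(
            root, "listOfSimulations",
            "uniformTimeCourse", "steadyState", "oneStep", "analysis", "simulation",
        ):
            sid = elem.get("id", "")
            algo = elem.find(f"{{{ns}}}algorithm")
            kisao = algo.get("kisaoID", "") if algo is not None else ""
            node = store.add_node(
                {g.SEDML_SIMULATION}, {"ID": sid, "SIMKISAO": kisao}
            )
            store.add_edge(anchor, node, HAS_SIMULATION)
            store.add_edge(node, anchor, g.BELONGS_TO)
            simulations[sid] = node
            report.simulations.append((node, kisao))
            if not kisao:
                report.warnings.append(f"simulation {sid!r} has no KiSAO algorithm id")

        # tasks pair a simulation with a model; repeatedTask flattens to leaves
        task_pairs: dict[str, tuple[str, str]] = {}
        tasks = children(root, "listOfTasks", "task", "repeatedTask")
        for elem in tasks:
            if etree.QName(elem).localname != "task":
                continue
            task_pairs[elem.get("id", "")] = (
                elem.get("simulationReference", ""),
                elem.get("modelReference", ""),
            )
        for elem in tasks:
            if etree.QName(elem).localname != "repeatedTask":
                continue
            leaves = []
            box = elem.find(f"{{{ns}}}listOfSubTasks")
            if box is not None:
                for sub in box:
                    ref = sub.get("task", "")
                    if ref in task_pairs:
                        leaves.append(task_pairs[ref])
            if leaves:
                task_pairs[elem.get("id", "")] = leaves[0]

        for task_id, (sim_ref, model_ref) in task_pairs.items():
            if sim_ref not in simulations or model_ref not in model_refs:
                raise SedmlImportError(
                    f"{filename}: task {task_id!r} references unknown "
                    f"simulation {sim_ref!r} or model {model_ref!r}"
                )
            store.add_edge(simulations[sim_ref], model_refs[model_ref], g.SIMULATES)

        for elem in children(root, "listOfDataGenerators", "dataGenerator"):
            dg = store.add_node({g.SEDML_DATAGENERATOR}, {"ID": elem.get("id", "")})
            store.add_edge(anchor, dg, HAS_DATAGENERATOR)
            store.add_edge(dg, anchor, g.BELONGS_TO)
            report.datagenerators += 1
            box = elem.find(f"{{{ns}}}listOfVariables")
            if box is None:
                continue
            for var in box.findall(f"{{{ns}}}variable"):
                task_ref = var.get("taskReference", "")
                model_ref_id = task_pairs.get(task_ref, ("", ""))[1]
                vnode = store.add_node(
                    {g.SEDML_VARIABLE},
                    {
                        "ID": var.get("id", ""),
                        "TARGET": var.get("target", var.get("symbol", "")),
                        "TASKREF": task_ref,
                        "MODELREF": model_ref_id,
                    },
                )
                store.add_edge(dg, vnode, "hasVariable")
                store.add_edge(vnode, dg, g.BELONGS_TO)
        return report
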