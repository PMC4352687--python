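"""Seeded synthetic corpora and reconstructed demonstration fixtures.

Every importer, linker and query in this package is testable without any
network access: :func:`generate_corpus` emits a deterministic set of
SBML, CellML and SED-ML files plus a mini ontology, together with a
:class:`GroundTruth` record of everything that was planted (entity
counts, annotation/concept pairs, simulation references, observation
targets, cross-format twin correspondences and decoys).

What the generator emulates: multi-entity SBML reaction networks with
MIRIAM annotations; CellML component/variable graphs with connections;
SED-ML files referencing stored models; and cross-format "twin" model
pairs that share a reference publication, with controlled name
perturbation for the implicit linker.  What it does not emulate:
biologically meaningful kinetics, real ontology semantics, or the size
and annotation idiosyncrasies of public repositories.

:func:`paper_fixtures` emits small hand-written files reconstructed from
published query results (a Tyson-1991-like SBML/CellML pair, an
Edelstein-1996-like pair, a Hog-pathway-like model, simulation
descriptions, SBO/GO/KiSAO slices and a resource-description table).
They are synthetic reconstructions for documentation and smoke tests,
not copies of the repository files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

from .similarity import levenshtein

_SBML_NS = "http://www.sbml.org/sbml/level2/version4"
_CELLML_NS = "http://www.cellml.org/cellml/1.0#"
_CMETA_NS = "http://www.cellml.org/metadata/1.0#"
_SEDML_NS = "http://sed-ml.org/"
_RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


class SyntheticSpecError(ValueError):
    """Impossible generator configuration."""


# ----------------------------------------------------------------------
# specs and ground truth
# ----------------------------------------------------------------------
@dataclass
class SyntheticSpec:
    """Conditions of a generated corpus (identical spec -> identical bytes)."""

    seed: int = 0
    n_models: int = 5
    species_range: tuple[int, int] = (5, 10)
    reaction_range: tuple[int, int] = (3, 8)
    compartment_range: tuple[int, int] = (1, 2)
    parameter_range: tuple[int, int] = (0, 3)
    annotation_density: float = 0.8
    twin_fraction: float = 0.4
    twin_exact_fraction: float = 2 / 3
    twin_decoy_fraction: float = 1 / 3
    name_perturbation: int = 1
    ontology_shape: tuple[int, int] = (3, 3)

    def validate(self) -> None:
        if not 0.0 <= self.annotation_density <= 1.0:
            raise SyntheticSpecError("annotation_density must lie in [0, 1]")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise SyntheticSpecError("twin_fraction must lie in [0, 1]")
        if self.twin_fraction > 0 and self.n_models < 2:
            raise SyntheticSpecError("twins require at least two models")
        if self.n_models < 1:
            raise SyntheticSpecError("n_models must be positive")
        for lo, hi in (self.species_range, self.reaction_range,
                       self.compartment_range, self.parameter_range):
            if lo > hi or lo < 0:
                raise SyntheticSpecError("invalid integer range")
        if self.species_range[0] < 1 or self.compartment_range[0] < 1:
            raise SyntheticSpecError("models need at least one species and compartment")
        if self.name_perturbation < 0:
            raise SyntheticSpecError("name_perturbation must be >= 0")


@dataclass
class TwinPair:
    sbml_entity: str
    cellml_entity: str
    kind: str  # exact | perturbed
    edit_distance: int


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by emitted filename."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    annotations: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    concept_links: list[tuple[str, str]] = field(default_factory=list)
    sedml_references: dict[str, list[str]] = field(default_factory=dict)
    observations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    changed_species: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    twins: dict[str, list[TwinPair]] = field(default_factory=dict)
    decoys: dict[str, list[str]] = field(default_factory=dict)
    publications: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=list)


# ----------------------------------------------------------------------
# names
# ----------------------------------------------------------------------
def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _distant(name: str, existing: list[str], min_ratio: float = 0.6) -> bool:
    return all(
        levenshtein(name, other) >= min_ratio * max(len(name), len(other))
        for other in existing
    )


def fresh_name(rng: random.Random, existing: list[str], n_syllables: int = 4) -> str:
    """Pronounceable name far (>= 60% length edit distance) from all others."""
    for _ in range(1000):
        name = _word(rng, n_syllables)
        if _distant(name, existing):
            existing.append(name)
            return name
    raise SyntheticSpecError("name space exhausted; reduce entity counts")


def perturb_name(rng: random.Random, name: str, budget: int, taken: list[str]) -> str:
    """Apply up to ``budget`` single-character edits, avoiding collisions."""
    alphabet = _CONSONANTS + _VOWELS
    for _ in range(1000):
        out = name
        for _ in range(max(1, budget)):
            op = rng.choice("sid")
            pos = rng.randrange(len(out)) if out else 0
            if op == "s" and out:
                out = out[:pos] + rng.choice(alphabet) + out[pos + 1:]
            elif op == "i":
                out = out[:pos] + rng.choice(alphabet) + out[pos:]
            elif out and len(out) > 2:
                out = out[:pos] + out[pos + 1:]
        if out != name and out not in taken:
            taken.append(out)
            return out
    raise SyntheticSpecError("could not perturb name without collision")


# ----------------------------------------------------------------------
# XML emitters (string templates; importers re-parse them)
# ----------------------------------------------------------------------
def _rdf_block(about: str, pairs: list[tuple[str, str]], indent: str = "  ") -> str:
    if not pairs:
        return ""
    by_qualifier: dict[str, list[str]] = {}
    for qualifier, uri in pairs:
        by_qualifier.setdefault(qualifier, []).append(uri)
    lines = [
        f'{indent}<rdf:RDF xmlns:rdf="{_RDF_NS}"',
        f'{indent}         xmlns:bqbiol="http://biomodels.net/biology-qualifiers/"',
        f'{indent}         xmlns:bqmodel="http://biomodels.net/model-qualifiers/">',
        f'{indent}  <rdf:Description rdf:about="{about}">',
    ]
    for qualifier in by_qualifier:
        ns = "bqmodel" if qualifier in ("isDescribedBy", "is", "isDerivedFrom", "isInstanceOf") and qualifier == "isDescribedBy" else "bqbiol"
        lines.append(f"{indent}    <{ns}:{qualifier}><rdf:Bag>")
        for uri in by_qualifier[qualifier]:
            lines.append(f'{indent}      <rdf:li rdf:resource="{uri}"/>')
        lines.append(f"{indent}    </rdf:Bag></{ns}:{qualifier}>")
    lines.append(f"{indent}  </rdf:Description>")
    lines.append(f"{indent}</rdf:RDF>")
    return "\n".join(lines)


def _sbml_annotation(meta_id: str, pairs: list[tuple[str, str]]) -> str:
    if not pairs:
        return ""
    return f"<annotation>\n{_rdf_block('#' + meta_id, pairs)}\n</annotation>"


def build_sbml(
    model_id: str,
    model_name: str,
    compartments: list[str],
    species: list[tuple[str, str]],
    reactions: list[tuple[str, list[str], list[str], list[str]]],
    parameters: list[str] = (),
    annotations: dict[str, list[tuple[str, str]]] | None = None,
) -> str:
    """Emit an SBML Level 2 document.

    ``species`` holds ``(id, compartment)`` pairs; ``reactions`` holds
    ``(id, reactants, products, modifiers)``; ``annotations`` maps an
    element id ("" for the model) to ``(qualifier, uri)`` pairs.
    """
    ann = annotations or {}

    def block(eid: str) -> str:
        return _sbml_annotation(f"meta_{eid or 'model'}", ann.get(eid, []))

    parts = [f'<?xml version="1.0" encoding="UTF-8"?>']
    parts.append(f'<sbml xmlns="{_SBML_NS}" level="2" version="4">')
    parts.append(f'<model id="{model_id}" name="{model_name}">')
    parts.append(block(""))
    parts.append("<listOfCompartments>")
    for cid in compartments:
        body = block(cid)
        if body:
            parts.append(f'<compartment id="{cid}" name="{cid}">{body}</compartment>')
        else:
            parts.append(f'<compartment id="{cid}" name="{cid}"/>')
    parts.append("</listOfCompartments>")
    parts.append("<listOfSpecies>")
    for sid, comp in species:
        body = block(sid)
        if body:
            parts.append(
                f'<species id="{sid}" name="{sid}" compartment="{comp}">{body}</species>'
            )
        else:
            parts.append(f'<species id="{sid}" name="{sid}" compartment="{comp}"/>')
    parts.append("</listOfSpecies>")
    if parameters:
        parts.append("<listOfParameters>")
        for pid in parameters:
            body = block(pid)
            if body:
                parts.append(f'<parameter id="{pid}" name="{pid}" value="1">{body}</parameter>')
            else:
                parts.append(f'<parameter id="{pid}" name="{pid}" value="1"/>')
        parts.append("</listOfParameters>")
    parts.append("<listOfReactions>")
    for rid, reactants, products, modifiers in reactions:
        parts.append(f'<reaction id="{rid}" name="{rid}">')
        parts.append(block(rid))
        if reactants:
            parts.append("<listOfReactants>")
            parts.extend(f'<speciesReference species="{s}"/>' for s in reactants)
            parts.append("</listOfReactants>")
        if products:
            parts.append("<listOfProducts>")
            parts.extend(f'<speciesReference species="{s}"/>' for s in products)
            parts.append("</listOfProducts>")
        if modifiers:
            parts.append("<listOfModifiers>")
            parts.extend(f'<modifierSpeciesReference species="{s}"/>' for s in modifiers)
            parts.append("</listOfModifiers>")
        parts.append("</reaction>")
    parts.append("</listOfReactions>")
    parts.append("</model>")
    parts.append("</sbml>")
    return "\n".join(p for p in parts if p)


def build_cellml(
    model_name: str,
    components: list[tuple[str, list[str]]],
    connections: list[tuple[str, str, list[tuple[str, str]]]],
    model_annotations: list[tuple[str, str]] = (),
    component_annotations: dict[str, list[tuple[str, str]]] | None = None,
) -> str:
    comp_ann = component_annotations or {}
    parts = ['<?xml version="1.0" encoding="UTF-8"?>']
    parts.append(
        f'<model xmlns="{_CELLML_NS}" xmlns:cmeta="{_CMETA_NS}" '
        f'name="{model_name}" cmeta:id="{model_name}">'
    )
    for cname, variables in components:
        parts.append(f'<component name="{cname}" cmeta:id="c_{cname}">')
        for vname in variables:
            parts.append(f'<variable name="{vname}" units="dimensionless"/>')
        parts.append("</component>")
    for c1, c2, pairs in connections:
        parts.append("<connection>")
        parts.append(f'<map_components component_1="{c1}" component_2="{c2}"/>')
        for v1, v2 in pairs:
            parts.append(f'<map_variables variable_1="{v1}" variable_2="{v2}"/>')
        parts.append("</connection>")
    rdf_parts = []
    if model_annotations:
        rdf_parts.append(("", list(model_annotations)))
    for cname, pairs in comp_ann.items():
        rdf_parts.append((f"#c_{cname}", pairs))
    if rdf_parts:
        parts.append(f'<rdf:RDF xmlns:rdf="{_RDF_NS}" '
                     'xmlns:bqbiol="http://biomodels.net/biology-qualifiers/" '
                     'xmlns:bqmodel="http://biomodels.net/model-qualifiers/">')
        for about, pairs in rdf_parts:
            by_q: dict[str, list[str]] = {}
            for q, uri in pairs:
                by_q.setdefault(q, []).append(uri)
            parts.append(f'<rdf:Description rdf:about="{about}">')
            for q, uris in by_q.items():
                ns = "bqmodel" if q == "isDescribedBy" else "bqbiol"
                parts.append(f"<{ns}:{q}><rdf:Bag>")
                parts.extend(f'<rdf:li rdf:resource="{u}"/>' for u in uris)
                parts.append(f"</rdf:Bag></{ns}:{q}>")
            parts.append("</rdf:Description>")
        parts.append("</rdf:RDF>")
    parts.append("</model>")
    return "\n".join(parts)


def build_sedml(
    models: list[tuple[str, str, str, list[str]]],
    simulations: list[tuple[str, str]],
    tasks: list[tuple[str, str, str]],
    datagenerators: list[tuple[str, list[tuple[str, str, str]]]],
) -> str:
    """Emit SED-ML Level 1 Version 1.

    ``models``: (id, source, language, change targets);
    ``simulations``: (id, kisao); ``tasks``: (id, simRef, modelRef);
    ``datagenerators``: (id, [(variable id, taskRef, xpath target)]).
    """
    parts = ['<?xml version="1.0" encoding="UTF-8"?>']
    parts.append(f'<sedML xmlns="{_SEDML_NS}" level="1" version="1">')
    parts.append("<listOfSimulations>")
    for sid, kisao in simulations:
        parts.append(
            f'<uniformTimeCourse id="{sid}" initialTime="0" outputStartTime="0" '
            f'outputEndTime="100" numberOfPoints="100">'
            f'<algorithm kisaoID="{kisao}"/></uniformTimeCourse>'
        )
    parts.append("</listOfSimulations>")
    parts.append("<listOfModels>")
    for mid, source, language, changes in models:
        if changes:
            parts.append(f'<model id="{mid}" language="{language}" source="{source}">')
            parts.append("<listOfChanges>")
            for target in changes:
                parts.append(f'<changeAttribute target="{target}" newValue="1"/>')
            parts.append("</listOfChanges>")
            parts.append("</model>")
        else:
            parts.append(f'<model id="{mid}" language="{language}" source="{source}"/>')
    parts.append("</listOfModels>")
    parts.append("<listOfTasks>")
    for tid, sim_ref, model_ref in tasks:
        parts.append(
            f'<task id="{tid}" simulationReference="{sim_ref}" modelReference="{model_ref}"/>'
        )
    parts.append("</listOfTasks>")
    parts.append("<listOfDataGenerators>")
    for dgid, variables in datagenerators:
        parts.append(f'<dataGenerator id="{dgid}"><listOfVariables>')
        for vid, task_ref, target in variables:
            parts.append(f'<variable id="{vid}" taskReference="{task_ref}" target="{target}"/>')
        parts.append("</listOfVariables></dataGenerator>")
    parts.append("</listOfDataGenerators>")
    parts.append("</sedML>")
    return "\n".join(parts)


def build_obo(
    ontology_tag: str, terms: list[tuple[str, str, str, list[str]]]
) -> str:
    """Emit an OBO 1.2 flat file: (id, name, definition, parent ids)."""
    parts = ["format-version: 1.2", f"ontology: {ontology_tag.lower()}", ""]
    for tid, name, definition, parents in terms:
        parts.append("[Term]")
        parts.append(f"id: {tid}")
        parts.append(f"name: {name}")
        if definition:
            parts.append(f'def: "{definition}" []')
        for parent in parents:
            parts.append(f"is_a: {parent}")
        parts.append("")
    return "\n".join(parts)


def _species_xpath(sid: str) -> str:
    return (
        "/sbml:sbml/sbml:model/sbml:listOfSpecies/"
        f"sbml:species[@id='{sid}']"
    )


def _cellml_var_xpath(component: str, variable: str) -> str:
    return (
        f"/cellml:model/cellml:component[@name='{component}']/"
        f"cellml:variable[@name='{variable}']"
    )


# ----------------------------------------------------------------------
# corpus generation
# ----------------------------------------------------------------------
def generate_corpus(spec: SyntheticSpec) -> tuple[dict[str, str], GroundTruth]:
    """Emit a deterministic file corpus and its ground truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    files: dict[str, str] = {}
    truth = GroundTruth()

    # --- mini ontology ------------------------------------------------
    depth, branching = spec.ontology_shape
    terms: list[tuple[str, str, str, list[str]]] = []
    next_num = [1]
    label_pool: list[str] = []

    def grow(parent: str | None, level: int) -> None:
        tid = f"SYN:{next_num[0]:07d}"
        next_num[0] += 1
        label = _word(rng, 3)
        label_pool.append(label)
        definition = f"{_word(rng, 2)} {_word(rng, 3)} {label}"
        terms.append((tid, label, definition, [parent] if parent else []))
        if level < depth:
            for _ in range(branching):
                grow(tid, level + 1)

    grow(None, 1)
    files["SYN.ontology.obo"] = build_obo("SYN", terms)
    truth.counts["SYN.ontology.obo"] = {"concepts": len(terms)}
    concept_ids = [t[0] for t in terms]

    def concept_uri(cid: str) -> str:
        return "urn:miriam:syn:" + cid.replace(":", "%3A")

    # --- models -------------------------------------------------------
    n_twins = round(spec.twin_fraction * spec.n_models)
    all_names: list[str] = []
    for i in range(spec.n_models):
        fname = f"syn_model_{i:02d}.sbml.xml"
        model_id = f"MDL{i:04d}"
        model_name = fresh_name(rng, all_names)
        n_species = rng.randint(*spec.species_range)
        n_reactions = rng.randint(*spec.reaction_range)
        n_compartments = rng.randint(*spec.compartment_range)
        n_parameters = rng.randint(*spec.parameter_range)
        compartments = [fresh_name(rng, all_names, 3) for _ in range(n_compartments)]
        species_names = [fresh_name(rng, all_names) for _ in range(n_species)]
        species = [(s, rng.choice(compartments)) for s in species_names]
        parameters = [fresh_name(rng, all_names, 3) for _ in range(n_parameters)]
        reactions = []
        for j in range(n_reactions):
            pool = list(species_names)
            rng.shuffle(pool)
            n_r = min(len(pool), rng.randint(1, 2))
            n_p = min(len(pool) - n_r, rng.randint(1, 2))
            reactants, pool = pool[:n_r], pool[n_r:]
            products, pool = pool[:n_p], pool[n_p:]
            modifiers = pool[:1] if pool and rng.random() < 0.5 else []
            reactions.append((f"re{j:02d}", reactants, products, modifiers))

        annotations: dict[str, list[tuple[str, str]]] = {}
        planted: list[tuple[str, str, str]] = []
        for s in species_names:
            if rng.random() < spec.annotation_density:
                cid = rng.choice(concept_ids)
                uri = concept_uri(cid)
                annotations[s] = [("is", uri)]
                planted.append((s, "is", uri))
                truth.concept_links.append((uri, cid))
        is_twin = i < n_twins
        pub_uri = ""
        if is_twin:
            pub_uri = f"urn:miriam:pubmed:9{i:06d}"
            annotations[""] = [("isDescribedBy", pub_uri)]
            truth.publications[fname] = pub_uri

        files[fname] = build_sbml(
            model_id, model_name, compartments, species, reactions, parameters, annotations
        )
        truth.counts[fname] = {
            "SBML_MODEL": 1,
            "SBML_SPECIES": n_species,
            "SBML_REACTION": n_reactions,
            "SBML_COMPARTMENT": n_compartments,
            "SBML_PARAMETER": n_parameters,
            "ANNOTATION": len(annotations),
        }
        truth.annotations[fname] = planted

        # --- CellML twin ---------------------------------------------
        cellml_fname = ""
        if is_twin:
            cellml_fname = f"syn_model_{i:02d}.cellml"
            n_exact = round(spec.twin_exact_fraction * n_species)
            n_decoys = round(spec.twin_decoy_fraction * n_species)
            pairs: list[TwinPair] = []
            components: list[tuple[str, list[str]]] = []
            comp_ann: dict[str, list[tuple[str, str]]] = {}
            for k, s in enumerate(species_names):
                if k < n_exact:
                    cname = s
                    pairs.append(TwinPair(s, cname, "exact", 0))
                else:
                    cname = perturb_name(rng, s, spec.name_perturbation, all_names)
                    pairs.append(
                        TwinPair(s, cname, "perturbed", levenshtein(s, cname))
                    )
                # perturbed twins lean on a shared annotation; exact twins
                # inherit it too when the species carries one
                for sp, q, uri in planted:
                    if sp == s:
                        comp_ann[cname] = [(q, uri)]
                components.append((cname, [cname, "time"]))
            decoys = [fresh_name(rng, all_names) for _ in range(n_decoys)]
            for d in decoys:
                components.append((d, [d, "time"]))
            components.append(("environment", ["time"]))
            connections = [
                (cname, "environment", [("time", "time")])
                for cname, _v in components[:-1]
            ]
            files[cellml_fname] = build_cellml(
                fname.replace(".sbml.xml", ""),
                components,
                connections,
                [("isDescribedBy", pub_uri)],
                comp_ann,
            )
            truth.twins[cellml_fname] = pairs
            truth.decoys[cellml_fname] = decoys
            truth.publications[cellml_fname] = pub_uri
            truth.counts[cellml_fname] = {
                "CELLML_MODEL": 1,
                "CELLMLCOMPONENT": len(components),
                "CELLMLVARIABLE": sum(len(v) for _c, v in components),
            }

        # --- SED-ML ---------------------------------------------------
        if is_twin or rng.random() < 0.5:
            sed_fname = f"syn_experiment_{i:02d}.sedml"
            observed = rng.sample(species_names, min(2, len(species_names)))
            changed = rng.choice(species_names)
            models = [("m0", fname, "urn:sedml:language:sbml",
                       [_species_xpath(changed)])]
            tasks = [("t0", "sim0", "m0")]
            variables = [
                (f"v{k}", "t0", _species_xpath(s)) for k, s in enumerate(observed)
            ]
            refs = [fname]
            if is_twin:
                models.append(("m1", cellml_fname, "urn:sedml:language:cellml", []))
                tasks.append(("t1", "sim0", "m1"))
                refs.append(cellml_fname)
            kisao = rng.choice(["KISAO:0000019", "KISAO:0000030", "KISAO:0000088"])
            datagens = [(f"dg{k}", [variables[k]]) for k in range(len(variables))]
            files[sed_fname] = build_sedml(models, [("sim0", kisao)], tasks, datagens)
            truth.sedml_references[sed_fname] = refs
            truth.observations[sed_fname] = [(fname, s) for s in observed]
            truth.changed_species[sed_fname] = [(fname, changed)]
            truth.counts[sed_fname] = {
                "SEDML_SIMULATION": 1,
                "SEDML_MODELREFERENCE": len(models),
                "SEDML_DATAGENERATOR": len(datagens),
            }
    return files, truth


def write_corpus(spec: SyntheticSpec, out_dir: str) -> GroundTruth:
    import os

    files, truth = generate_corpus(spec)
    os.makedirs(out_dir, exist_ok=True)
    for name, content in files.items():
        with open(os.path.join(out_dir, name), "w", encoding="utf-8") as fh:
            fh.write(content)
    with open(os.path.join(out_dir, "ground_truth.json"), "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    return truth


# ----------------------------------------------------------------------
# reconstructed demonstration fixtures
# ----------------------------------------------------------------------
#: the twelve ligand-binding-state species of the Edelstein 1996
#: acetylcholine-receptor models (reconstruction)
EDELSTEIN_SPECIES = [
    "ALL", "I", "DL", "ILL", "D", "DLL", "B", "BL", "A", "AL", "IL", "BLL",
]

TYSON_COMPONENTS = [
    "YP", "Y", "M", "pM", "CP", "C2", "environment", "reaction_constants",
]

GO_ACH_CHANNEL = "urn:miriam:obo.go:GO%3A0005892"
PUBMED_TYSON = "urn:miriam:pubmed:1831270"

#: resources whose descriptions mention "M-phase inducer phosphatase"
MPHASE_RESOURCES = [
    "urn:miriam:interpro:IPR000751",
    "urn:miriam:ec-code:3.1.3.48",
    "urn:miriam:uniprot:P30311",
    "urn:miriam:uniprot:P23748",
    "urn:miriam:uniprot:P20483",
    "urn:miriam:uniprot:P06652",
    "urn:miriam:uniprot:P30304",
]


def _edelstein_sbml(model_id: str, name: str, rich: bool) -> str:
    """Synthetic reconstruction of an Edelstein-like receptor model.

    With ``rich`` the annotation layout plants 104 annotations over 65
    elements (12 species, 17 reactions, 1 compartment, 35 parameters);
    otherwise only the species annotations are emitted.
    """
    species = [(s, "comp1") for s in EDELSTEIN_SPECIES]
    reactions = []
    for j in range(17):
        a = EDELSTEIN_SPECIES[j % 12]
        b = EDELSTEIN_SPECIES[(j + 1) % 12]
        reactions.append((f"React{j}", [a], [b], []))
    parameters = [f"kf_{j}" for j in range(35)] if rich else []
    annotations: dict[str, list[tuple[str, str]]] = {
        s: [("isVersionOf", GO_ACH_CHANNEL)] for s in EDELSTEIN_SPECIES
    }
    annotations[""] = [("isDescribedBy", "urn:miriam:pubmed:8983160")]
    if rich:
        # species: 33 annotations (ALL carries 3, eight carry 3, three carry 2)
        annotations["ALL"] += [
            ("hasPart", "urn:miriam:interpro:IPR002394"),
            ("hasProperty", "urn:miriam:biomodels.sbo:SBO%3A0000297"),
        ]
        for s in EDELSTEIN_SPECIES[1:9]:
            annotations[s] += [
                ("hasPart", "urn:miriam:interpro:IPR002394"),
                ("hasProperty", "urn:miriam:biomodels.sbo:SBO%3A0000297"),
            ]
        for s in EDELSTEIN_SPECIES[9:12]:
            annotations[s] += [("hasProperty", "urn:miriam:biomodels.sbo:SBO%3A0000297")]
        # reactions: 34, compartment: 2, parameters: 35 -> 104 in total
        for rid, _r, _p, _m in reactions:
            annotations[rid] = [
                ("is", "urn:miriam:biomodels.sbo:SBO%3A0000177"),
                ("isVersionOf", "urn:miriam:obo.go:GO%3A0007274"),
            ]
        annotations["comp1"] = [
            ("is", "urn:miriam:obo.go:GO%3A0005886"),
            ("isVersionOf", "urn:miriam:biomodels.sbo:SBO%3A0000290"),
        ]
        for pid in parameters:
            annotations[pid] = [("is", "urn:miriam:biomodels.sbo:SBO%3A0000009")]
    return build_sbml(model_id, name, ["comp1"], species, reactions, parameters, annotations)


def _tyson_sbml() -> str:
    species = [(s, "Cell") for s in ("C2", "CP", "M", "pM", "Y", "YP")]
    reactions = [
        ("Reaction1", ["Y"], ["YP"], []),
        ("Reaction2", ["CP", "Y"], ["pM"], []),
        ("Reaction3", ["pM"], ["M"], ["CP"]),
        ("Reaction4", ["M"], ["C2"], []),
        ("Reaction5", ["C2"], ["CP"], []),
    ]
    annotations = {
        "": [("isDescribedBy", PUBMED_TYSON)],
        "pM": [("hasPart", "urn:miriam:interpro:IPR001763")],
        "CP": [("is", "urn:miriam:uniprot:P06652")],
        "M": [("isVersionOf", "urn:miriam:obo.go:GO%3A0007049")],
    }
    return build_sbml(
        "BIOMD0000000005", "Tyson1991 - Cell Cycle 6 var", ["Cell"],
        species, reactions, ["k1aa", "k4"], annotations,
    )


def _tyson_cellml() -> str:
    # 68 variables over the eight components of the published encoding
    sizes = {
        "YP": 9, "Y": 9, "M": 9, "pM": 9, "CP": 9, "C2": 9,
        "environment": 1, "reaction_constants": 13,
    }
    components = []
    for cname in TYSON_COMPONENTS:
        variables = [cname] if cname != "environment" else []
        variables += ["time"] if cname != "reaction_constants" else []
        k = 0
        while len(variables) < sizes[cname]:
            variables.append(f"{cname}_v{k}")
            k += 1
        components.append((cname, variables[: sizes[cname]]))
    connections = [
        (cname, "environment", [("time", "time")])
        for cname in TYSON_COMPONENTS
        if cname not in ("environment", "reaction_constants")
    ]
    component_annotations = {"CP": [("is", "urn:miriam:uniprot:P06652")]}
    return build_cellml(
        "tyson_1991", components, connections,
        [("isDescribedBy", PUBMED_TYSON)], component_annotations,
    )


def _tyson_sedml() -> str:
    models = [
        ("model_sbml", "tyson1991_cellcycle.reconstructed.sbml.xml",
         "urn:sedml:language:sbml", [_species_xpath("YP")]),
        ("model_cellml", "tyson_1991.reconstructed.cellml",
         "urn:sedml:language:cellml", []),
    ]
    simulations = [("sim0", "KISAO:0000019")]
    tasks = [
        ("task_sbml", "sim0", "model_sbml"),
        ("task_cellml", "sim0", "model_cellml"),
    ]
    datagenerators = [
        ("dg_cp_sbml", [("v_cp_sbml", "task_sbml", _species_xpath("CP"))]),
        ("dg_cp_cellml", [("v_cp_cellml", "task_cellml", _cellml_var_xpath("CP", "CP"))]),
    ]
    return build_sedml(models, simulations, tasks, datagenerators)


def _hog_sbml() -> str:
    """Synthetic reconstruction of a Hog-pathway-like model: one species
    acting purely as a modifier of ten reactions."""
    names = ["Hog1PPActive", "Hog1", "Hog1PP", "Pbs2", "Pbs2PP", "Glycerol",
             "Sln1", "Sho1", "Fps1", "ProteinX"]
    species = [(s, "cell") for s in names]
    reactions = []
    for j in range(10):
        a = names[1 + (j % 5)]
        b = names[1 + ((j + 1) % 5)]
        reactions.append((f"v{j}", [a], [b], ["Hog1PPActive"]))
    # competing modifiers that also act as reactants, and a weaker pure one
    reactions.append(("v10", ["Glycerol"], ["Fps1"], ["Pbs2PP"]))
    reactions.append(("v11", ["Sln1"], ["Sho1"], ["ProteinX"]))
    reactions.append(("v12", ["Sho1"], ["Sln1"], ["ProteinX"]))
    annotations = {"": [("isDescribedBy", "urn:miriam:pubmed:22962472")]}
    return build_sbml(
        "BIOMD0000000429", "Schaber2012 - Hog pathway in yeast", ["cell"],
        species, reactions, [], annotations,
    )


def _novak_sbml() -> str:
    species = [(s, "cell") for s in ("CycB", "Cdc2", "MPF", "Cdc25")]
    reactions = [
        ("r1", ["CycB", "Cdc2"], ["MPF"], []),
        ("r2", ["MPF"], ["CycB"], ["Cdc25"]),
    ]
    annotations = {
        "": [("isDescribedBy", "urn:miriam:pubmed:9096356")],
        "Cdc25": [("is", "urn:miriam:uniprot:P30304")],
    }
    return build_sbml(
        "BIOMD0000000007", "Novak1997 - Cell Cycle", ["cell"],
        species, reactions, [], annotations,
    )


def _novak_sedml(which: str) -> str:
    models = [("m0", "novak1997_cellcycle.reconstructed.sbml.xml",
               "urn:sedml:language:sbml", [])]
    simulations = [("sim0", "KISAO:0000035")]
    tasks = [("t0", "sim0", "m0")]
    datagenerators = [
        (f"dg_{which}", [(f"v_{which}", "t0", _species_xpath("Cdc25"))])
    ]
    return build_sedml(models, simulations, tasks, datagenerators)


def _sbo_slice() -> str:
    terms = [
        ("SBO:0000000", "systems biology representation", "root term", []),
        ("SBO:0000009", "kinetic constant",
         "numerical parameter that quantifies the velocity of a chemical reaction",
         ["SBO:0000000"]),
        ("SBO:0000331", "half-life", "time for half decay", ["SBO:0000009"]),
        ("SBO:0000332", "diffusion coefficient", "diffusion rate parameter", ["SBO:0000009"]),
        ("SBO:0000333", "bimolecular rate constant",
         "kinetic constant of a bimolecular reaction", ["SBO:0000009"]),
        ("SBO:0000252", "polypeptide chain", "amino acid polymer", ["SBO:0000000"]),
        ("SBO:0000290", "physical compartment", "bounded volume", ["SBO:0000000"]),
        ("SBO:0000297", "protein complex", "macromolecular complex of proteins", ["SBO:0000000"]),
        ("SBO:0000177", "non-covalent binding", "reversible association", ["SBO:0000000"]),
    ]
    return build_obo("SBO", terms)


def _go_slice() -> str:
    terms = [
        ("GO:0008150", "biological_process", "root process", []),
        ("GO:0005575", "cellular_component", "root component", []),
        ("GO:0005892", "acetylcholine-gated channel complex",
         "plasma membrane protein complex forming an acetylcholine-gated ion channel",
         ["GO:0005575"]),
        ("GO:0005886", "plasma membrane", "membrane surrounding the cell", ["GO:0005575"]),
        ("GO:0007049", "cell cycle",
         "progression of biochemical and morphological phases between cell divisions",
         ["GO:0008150"]),
        ("GO:0007274", "neuromuscular synaptic transmission",
         "signal transmission at the neuromuscular junction", ["GO:0008150"]),
        ("GO:0043241", "protein complex disassembly",
         "disaggregation of a protein complex", ["GO:0008150"]),
    ]
    return build_obo("GO", terms)


def _kisao_slice() -> str:
    terms = [
        ("KISAO:0000000", "kinetic simulation algorithm", "root algorithm", []),
        ("KISAO:0000019", "CVODE",
         "stiff and nonstiff ordinary differential equation solver from the "
         "Livermore solver family", ["KISAO:0000000"]),
        ("KISAO:0000030", "Euler forward method", "explicit first order method",
         ["KISAO:0000000"]),
        ("KISAO:0000035", "generalized stochastic simulation algorithm",
         "stochastic kinetic simulation", ["KISAO:0000000"]),
        ("KISAO:0000088", "LSODA",
         "Livermore solver switching between stiff and nonstiff methods",
         ["KISAO:0000000"]),
    ]
    return build_obo("KISAO", terms)


def _resource_descriptions() -> str:
    phosphatase = "M-phase inducer phosphatase"
    lines = ["# URI<TAB>description (synthetic stand-in for web look-ups)"]
    descriptions = {
        "urn:miriam:interpro:IPR000751": f"{phosphatase} family signature",
        "urn:miriam:ec-code:3.1.3.48": f"protein-tyrosine-phosphatase; {phosphatase} activity",
        "urn:miriam:uniprot:P30311": f"{phosphatase} homolog, Xenopus",
        "urn:miriam:uniprot:P23748": f"{phosphatase} cdc25, Xenopus",
        "urn:miriam:uniprot:P20483": f"{phosphatase} string (cdc25), Drosophila",
        "urn:miriam:uniprot:P06652": f"{phosphatase} cdc25, fission yeast",
        "urn:miriam:uniprot:P30304": f"{phosphatase} cdc25A, human",
        "urn:miriam:interpro:IPR001763": "Rhodanese-like domain, diphthine synthase related",
        "urn:miriam:interpro:IPR002394": "Nicotinic acetylcholine receptor signature",
    }
    for uri, text in descriptions.items():
        lines.append(f"{uri}\t{text}")
    return "\n".join(lines)


def paper_fixtures() -> dict[str, str]:
    """Bundled reconstructed fixtures (filename -> file content).

    All files are synthetic reconstructions built from published query
    results, intended for documentation and smoke tests.
    """
    return {
        "edelstein1996_event.reconstructed.sbml.xml": _edelstein_sbml(
            "BIOMD0000000001", "Edelstein1996 - EPSP ACh event", rich=True
        ),
        "edelstein1996_species.reconstructed.sbml.xml": _edelstein_sbml(
            "BIOMD0000000002", "Edelstein1996 - EPSP ACh species", rich=False
        ),
        "tyson1991_cellcycle.reconstructed.sbml.xml": _tyson_sbml(),
        "tyson_1991.reconstructed.cellml": _tyson_cellml(),
        "tyson1991.reconstructed.sedml": _tyson_sedml(),
        "schaber2012_hog.reconstructed.sbml.xml": _hog_sbml(),
        "novak1997_cellcycle.reconstructed.sbml.xml": _novak_sbml(),
        "novak1997_fig2a.reconstructed.sedml": _novak_sedml("fig2a"),
        "novak1997_fig2b.reconstructed.sedml": _novak_sedml("fig2b"),
        "sbo.slice.obo": _sbo_slice(),
        "go.slice.obo": _go_slice(),
        "kisao.slice.obo": _kisao_slice(),
        "resource_descriptions.synthetic.tsv": _resource_descriptions(),
    }
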