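"""Cross-domain linking: ontology suffix matching, SED-ML resolution,
observation targets, and implicit cross-format entity links."""

import io
import random

import pytest

from modelgraph import PropertyGraph
from modelgraph import graph as g
from modelgraph.corpus import import_corpus
from modelgraph.linking import (
    LinkerError,
    infer_cross_format_links,
    link_annotations_to_ontology,
    link_datagenerators_to_entities,
    link_sedml_to_models,
)
from modelgraph.ontology import OntologyImporter, find_concept
from modelgraph.synthetic import SyntheticSpec, build_obo, generate_corpus, paper_fixtures


def _fresh_fixture_store():
    store = PropertyGraph()
    import_corpus(store, paper_fixtures())
    return store


class TestLinkTypeA:
    def test_sbo_resource_links_to_kinetic_constant(self):
        store = _fresh_fixture_store()
        n = link_annotations_to_ontology(store, "SBO")
        assert n >= 1
        concept = find_concept(store, "SBO:0000009")
        (res,) = store.nodes_by_attribute(
            g.RESOURCE, "URI", "urn:miriam:biomodels.sbo:SBO%3A0000009"
        )
        assert store.has_edge(res, concept, g.IS_ONTOLOGY_ENTRY)
        # description text is enriched with the concept label for the index
        assert "kinetic constant" in str(store.get(res, "RESOURCETEXT"))

    def test_no_matching_resources_returns_zero(self):
        store = PropertyGraph()
        OntologyImporter(store).import_file(
            io.BytesIO(paper_fixtures()["sbo.slice.obo"].encode()), "SBO"
        )
        assert link_annotations_to_ontology(store, "SBO") == 0

    def test_unknown_tag_rejected(self):
        with pytest.raises(LinkerError):
            link_annotations_to_ontology(PropertyGraph(), "NOPE")

    def test_ambiguous_suffix_match_is_an_error(self):
        store = PropertyGraph()
        terms = [
            ("Q:0000001", "a", "", []),
            ("QX0000001", "b", "", []),  # same 7-char suffix, different id
        ]
        OntologyImporter(store).import_file(io.BytesIO(build_obo("Q", terms).encode()), "Q")
        store.add_node({g.RESOURCE}, {"URI": "urn:miriam:q:Q%3A0000001", "KEY": "q:Q:0000001"})
        with pytest.raises(LinkerError, match="multiple"):
            link_annotations_to_ontology(store, "Q")

    @pytest.mark.parametrize("seed", range(3))
    def test_count_equals_quadratic_suffix_oracle(self, seed):
        rng = random.Random(seed)
        store = PropertyGraph()
        n_concepts = 30
        terms = [(f"R:{i + 1:07d}", f"t{i}", "", []) for i in range(n_concepts)]
        OntologyImporter(store).import_file(io.BytesIO(build_obo("R", terms).encode()), "R")
        uris = []
        for i in range(50):
            if i < 20:  # planted matches
                cid = rng.randrange(1, n_concepts + 1)
                uris.append(f"urn:miriam:r:R%3A{cid:07d}")
            else:  # decoys: wrong tag or nonexistent accession
                if rng.random() < 0.5:
                    uris.append(f"urn:miriam:other:Z%3A{rng.randrange(10 ** 7):07d}")
                else:
                    uris.append(f"urn:miriam:r:R%3A{rng.randrange(1000, 2000) + 10 ** 6:07d}")
        for i, uri in enumerate(uris):
            store.add_node({g.RESOURCE}, {"URI": uri, "KEY": f"k{i}", "RESOURCETEXT": ""})

        concept_ids = [t[0] for t in terms]
        oracle = sum(
            1
            for uri in uris
            if "R" in uri and sum(1 for c in concept_ids if c[-7:] == uri[-7:]) == 1
        )
        assert link_annotations_to_ontology(store, "R") == oracle
        assert oracle == 20


class TestLinkTypeB:
    def test_both_tyson_encodings_resolved(self):
        store = _fresh_fixture_store()
        records, unresolved = link_sedml_to_models(store)
        tyson = [r for r in records if "tyson" in str(store.get(r.source, "MODELSOURCE"))]
        assert len(tyson) == 2
        assert all(r.confidence == 1.0 for r in records)

    def test_absent_model_reported_unresolved(self):
        store = PropertyGraph()
        from modelgraph.synthetic import build_sedml
        from modelgraph.sedml import SedmlImporter

        content = build_sedml(
            [("m0", "missing_model.xml", "urn:sedml:language:sbml", [])],
            [("s0", "KISAO:0000019")], [("t0", "s0", "m0")], [],
        )
        SedmlImporter(store).import_file(io.BytesIO(content.encode()), "e.sedml")
        records, unresolved = link_sedml_to_models(store)
        assert records == []
        assert unresolved == ["missing_model.xml"]

    @pytest.mark.parametrize("seed", range(3))
    def test_generated_reference_targets_match_ground_truth(self, seed):
        files, truth = generate_corpus(SyntheticSpec(seed=seed, n_models=4))
        store = PropertyGraph()
        import_corpus(store, files)
        link_sedml_to_models(store)
        for sed_name, targets in truth.sedml_references.items():
            (sed_doc,) = store.nodes_by_attribute(g.DOCUMENT, "FILENAME", sed_name)
            refs = [
                r for r in store.traverse([sed_doc], g.BELONGS_TO, "in", 2, 2)
                if g.SEDML_MODELREFERENCE in store.labels(r)
            ]
            resolved_docs = set()
            for ref in refs:
                for m in store.neighbors(ref, g.REFERENCES_SIMULATION_MODEL, "out"):
                    for doc in store.neighbors(m, g.BELONGS_TO, "out"):
                        resolved_docs.add(str(store.get(doc, "FILENAME")))
            assert resolved_docs == set(targets)


class TestLinkTypeC:
    def test_observes_edge_to_cp_in_both_encodings(self):
        store = _fresh_fixture_store()
        link_sedml_to_models(store)
        records, _unresolved = link_datagenerators_to_entities(store)
        observed_names = {str(store.get(r.target, "NAME")) for r in records}
        assert "CP" in observed_names
        cp_links = [r for r in records if store.get(r.target, "NAME") == "CP"]
        observed_labels = {
            lab for r in cp_links for lab in store.labels(r.target)
        }
        assert g.SBML_SPECIES in observed_labels  # SBML encoding
        assert observed_labels & {g.CELLML_COMPONENT, g.CELLML_VARIABLE}  # CellML encoding

    def test_change_target_flags_species(self):
        store = _fresh_fixture_store()
        link_sedml_to_models(store)
        link_datagenerators_to_entities(store)
        (yp,) = [
            s for s in store.nodes_by_attribute(g.SBML_SPECIES, "ID", "YP")
            if store.get(_model_of(store, s), "NAME") == "Tyson1991 - Cell Cycle 6 var"
        ]
        assert store.get(yp, "IS_CHANGED") is True

    @pytest.mark.parametrize("seed", range(3))
    def test_generated_observation_targets_match_ground_truth(self, seed):
        files, truth = generate_corpus(SyntheticSpec(seed=seed, n_models=4))
        store = PropertyGraph()
        import_corpus(store, files)
        link_sedml_to_models(store)
        records, unresolved = link_datagenerators_to_entities(store)
        assert unresolved == []
        observed = {
            (_doc_name(store, r.target), str(store.get(r.target, "ID")))
            for r in records
            if g.SBML_SPECIES in store.labels(r.target)
        }
        expected = {
            pair for pairs in truth.observations.values() for pair in pairs
        }
        assert observed == expected


def _model_of(store, node):
    for m in store.neighbors(node, g.BELONGS_TO, "out"):
        if store.labels(m) & {g.SBML_MODEL, g.CELLML_MODEL}:
            return m
    return None


def _doc_name(store, entity):
    docs = store.traverse([entity], g.BELONGS_TO, "out", 1, None)
    for d in docs:
        if g.DOCUMENT in store.labels(d):
            return str(store.get(d, "FILENAME"))
    return ""


class TestLinkTypeD:
    def test_equally_named_entities_of_shared_publication_linked(self):
        store = _fresh_fixture_store()
        records = infer_cross_format_links(store)
        by_names = {
            (str(store.get(r.source, "NAME")), str(store.get(r.target, "NAME")))
            for r in records
        }
        assert ("C2", "C2") in by_names
        c2 = [r for r in records
              if store.get(r.source, "NAME") == "C2" and g.CELLML_COMPONENT in store.labels(r.target)]
        assert c2 and c2[0].confidence >= 0.7
        assert "shared publication" in c2[0].evidence

    def test_no_shared_publication_no_links(self):
        files = {
            k: v for k, v in paper_fixtures().items()
            if k in ("edelstein1996_event.reconstructed.sbml.xml",)
        }
        # CellML twin with identical names but a different publication
        from modelgraph.synthetic import build_cellml, EDELSTEIN_SPECIES

        files["other.cellml"] = build_cellml(
            "other", [(s, [s]) for s in EDELSTEIN_SPECIES], [],
            [("isDescribedBy", "urn:miriam:pubmed:999999")],
        )
        store = PropertyGraph()
        import_corpus(store, files)
        assert infer_cross_format_links(store, threshold=0.0) == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(LinkerError):
            infer_cross_format_links(PropertyGraph(), threshold=1.5)

    def test_confidence_monotone_in_name_similarity(self):
        from modelgraph.similarity import name_similarity

        weights = (0.7, 0.3)
        for ann in (0.0, 1.0):
            sims = [name_similarity("kinase", x) for x in ("kinase", "kinasa", "kixxsa")]
            scores = [weights[0] * s + weights[1] * ann for s in sims]
            assert scores == sorted(scores, reverse=True)


class TestIdempotence:
    def test_running_all_linkers_twice_creates_nothing_new(self):
        store = _fresh_fixture_store()
        from modelgraph.corpus import link_all

        link_all(store)
        edges_before = store.n_edges
        counts = link_all(store)
        assert store.n_edges == edges_before
        assert counts == {"a": 0, "b": 0, "c": 0, "d": 0}
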