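# Methods

## The graph schema

Every imported file gets a `DOCUMENT` root node carrying the filename.
Model content hangs below it:

* **SBML**: `DOCUMENT -hasModel-> SBML_MODEL`, which fans out via
  `hasSpecies` / `hasReaction` / `hasCompartment` / `hasParameter` /
  `hasFunction`. Reaction participation is encoded on the species side:
  `SBML_SPECIES -IS_REACTANT|IS_PRODUCT|IS_MODIFIER-> SBML_REACTION`
  (one edge per role with a summed `stoichiometry` attribute if a
  species appears twice in the same role). Species sit in their
  compartment via `isContainedIn`. Events and rules map to generic
  `SBML_ELEMENT` nodes. Unit definitions are skipped and reported;
  kinetic-law MathML is stored verbatim as a text attribute (`MATH`)
  because no supported query needs its structure.
* **CellML** (1.0/1.1): `CELLML_MODEL -hasComponent-> CELLMLCOMPONENT
  -hasVariable-> CELLMLVARIABLE`; each `map_variables` entry of a
  connection becomes one `MAPPED_TO` edge, directed from the
  first-listed component to the second but treated as undirected by all
  matching, since CellML connections are symmetric. CellML 1.2+/2.0 is
  rejected.
* **SED-ML** (Level 1): a `SEDML` anchor under the document holds
  `SEDML_MODELREFERENCE` (with `MODELSOURCE` verbatim),
  `SEDML_SIMULATION` (with `SIMKISAO` from the algorithm's KiSAO id),
  `SEDML_DATAGENERATOR` and `SEDML_VARIABLE` (XPath `TARGET` verbatim)
  nodes. Tasks become `SIMULATES` edges simulation → model reference;
  `repeatedTask` is flattened onto its leaf tasks. Model references and
  simulations sit exactly two `BELONGS_TO` hops above the document,
  which fixes the hop counts used by the canned experiment queries.
* **Ontologies** (OBO 1.2 via obonet, or a pragmatic OWL RDF/XML subset:
  named classes, `rdfs:label`, `rdfs:subClassOf` between named classes,
  IAO definition texts): one node per concept, labelled
  `<tag>Ontology` (e.g. `SBOOntology`), `isA` edges child → parent, an
  `ONTOLOGY_ROOT` anchor per ontology. Only subsumption is mapped;
  other relationship types are dropped and counted. A cyclic `isA`
  hierarchy is an import error. No description-logic reasoning is
  performed — every supported query needs only the transitive `isA`
  closure.

**Upward edges.** Every created node points to its parent through a
single edge type `BELONGS_TO`, and annotation containers and resources
participate in the same scheme (see below). One uniform type keeps
variable-length upward traversals (`BELONGS_TO*1..2`, unbounded `*`)
well-defined across node kinds; the validator checks that every
document-owned node reaches exactly one `DOCUMENT` root.

**Annotations.** An annotated element gets one `ANNOTATION` container:
`element -hasAnnotation-> annotation -BELONGS_TO-> element`; each
qualified reference becomes `annotation -<qualifier>-> resource`
(`is`, `isVersionOf`, `hasPart`, `isDescribedBy`, ...) plus
`resource -BELONGS_TO-> annotation`. This double bookkeeping lets
queries enter from either end — from an element down to its resources,
or from a resource up to every element using it — without undirected
matching. `RESOURCE` nodes are deduplicated on a canonical
`(collection, accession)` key so that MIRIAM URNs and identifiers.org
URLs of the same record share one node; PubMed resources additionally
carry the `PUBLICATION` label, which is what makes reference
publications shared between a model's SBML and CellML encodings.
Simulation-algorithm references are deliberately *not* resources: they
live in the `SIMKISAO` attribute, where the algorithm-filter query
reads them.

## Link types

1. **Annotation → ontology concept.** A resource participates if its
   URI contains the ontology tag (case-sensitive); it is linked
   (`IS_ONTOLOGY_ENTRY`) to the concept whose id shares its last
   **7** characters. Seven works uniformly because SBO, GO and KiSAO
   accessions are zero-padded to seven digits. A resource matching two
   concepts is an error, never a silent pick. Newly linked resources
   get the concept's label and definition appended to their
   `RESOURCETEXT`, which feeds the full-text index. The suffix length
   is configurable (`suffix_match_length`).
2. **SED-ML → model.** `MODELSOURCE` resolution order: exact match on a
   stored document `FILENAME`, then exact match on a model `ID`
   attribute, then document basename; the first hit wins and ambiguity
   is reported. Unresolved references are reported, not fatal.
3. **Data generator → entity.** The variable's XPath target is resolved
   inside the models its reference links to. The supported XPath
   dialect is descendant selectors with `[@id='...']` / `[@name='...']`
   predicates — the dialect SED-ML uses in practice on SBML and CellML;
   anything else lands in the unresolved report. The last predicate
   value is looked up among the model's entities by `ID`, then by
   `NAME` (disambiguated by the enclosing component name for CellML).
   Matches create `OBSERVES` edges; change targets set
   `IS_CHANGED=true` on the addressed species.
4. **Implicit cross-format links.** Gating condition: two models of
   different formats must share a reference publication. Candidate
   pairs are SBML species/compartments/parameters × CellML
   components/variables. Score:

       score = 0.7 · sim(a, b) + 0.3 · [shared annotation resource]
       sim(a, b) = 1 − lev(fold(a), fold(b)) / max(|fold(a)|, |fold(b)|)

   where `fold` case-folds and Porter-stems each alphabetic run and
   `lev` is the Levenshtein distance (edlib). Pairs at or above the
   threshold (default **0.7**) survive; each entity keeps only its
   best-scoring counterpart (ties broken lexicographically by the
   counterpart's name), and the symmetric edge is stored once with the
   score as its `confidence` attribute. The weights, threshold and
   best-match policy are this package's design choices — the linking
   idea (shared publication + name similarity + annotation overlap)
   does not itself prescribe numbers — and all are configurable. Note
   the consequence: with these weights an exact name alone is exactly
   at the 0.7 threshold, and a name at edit distance 1 passes only when
   the entities also share an annotation.

All four linkers are idempotent (existing edges are never duplicated),
so linking is safe to re-run after every import. Explicit links (a–c)
carry confidence 1.0.

## Queries

The query layer is a programmatic API, not a query-language parser: the
store's semantics, not a host syntax, are the point. A linear pattern
is a list of steps (label filter, edge type, direction, hop bounds,
attribute filters with `equals`/`regex`/`contains`, optional negation);
matching seeds on the first step's label index and extends by
traversal. Variable-length hops use walk semantics (a node qualifies if
some walk of an in-range length reaches it), implemented cycle-safely
by visiting (node, depth) pairs; an unbounded upper bound is capped at
`min_hops + |V|`, which is exact because any longer walk can be
cycle-shortened into that window. Regex filters are unanchored and
case-sensitive. Row order is deterministic (sorted node ids), so
identical stores serialize identical results.

Sixteen canned queries cover the repository use cases: model look-ups
by format/name, species and component listings, per-element annotation
tables, URI-regex annotation search, simulations applicable to a model,
models runnable by a given algorithm, experiments observing an
annotated species in a given reaction role (three simultaneous
filters), top annotations, subsumption-closure annotation counts, and
min/max/avg/stdev statistics.

Statistics use the **sample** standard deviation (n−1); a single
observation reports 0.0. Groups are formed only from entities the
pattern actually matches, so models without annotations (or components
without variables) do not contribute zero rows — mirroring what a
pattern-matching query engine would return.

The full-text index covers `RESOURCETEXT` (URI local part, appended
ontology label + definition, optional description tables standing in
for web look-ups). Scoring is plain TF-IDF with log-scaled term
frequency and smoothed idf,
`(1 + log tf) · (1 + log((1+N)/(1+df)))`, conjunctive over query
tokens, ties broken by URI. This deliberately replaces a full
ranked-retrieval engine; the smoothing keeps idf positive even for a
token present in every description, so term frequency always
discriminates.

## Synthetic data

`generate_corpus(SyntheticSpec(...))` emits a deterministic corpus
(identical spec → identical bytes): SBML reaction networks, CellML
twins, SED-ML experiments, a mini ontology, and a `GroundTruth` record
of every planted fact. Defaults: 5 models, 5–10 species, 3–8 reactions,
1–2 compartments, 0–3 global parameters per model, annotation density
0.8 (the fraction of species carrying an ontology annotation — public
curated models are richly but not exhaustively annotated), twin
fraction 0.4, ontology of depth 3 and branching 3, name perturbation
budget 1 edit.

Entity names come from a pronounceable consonant-vowel generator with
rejection sampling that keeps all independent names at ≥ 60 % of their
length in edit distance from each other; twin entities are either exact
copies or perturbed by the edit budget. This makes the matcher's task
well-posed: planted pairs are the unique near neighbours, decoys are
provably distant. Perturbed twins inherit their species' ontology
annotation, reflecting that two encodings of one model annotate the
same biology.

What the generator does **not** emulate: meaningful kinetics or MathML
semantics, real ontology content, the annotation idiosyncrasies and
scale of public repositories, CellML 1.1 import hierarchies. Passing
tests therefore demonstrate the correctness of the mapping, linking and
query machinery under controlled conditions, not retrieval quality on
real repository corpora.

The bundled demonstration files are *reconstructions* of well-known
repository entries, built from their published structure (species id
lists, component names, qualifier usage, entity counts); where only an
aggregate was published, the reconstruction plants exactly that
aggregate. They exercise the same code paths as the originals but are
synthetic stand-ins, clearly marked `reconstructed`/`synthetic` in
their filenames.

## Numerical and engineering choices

* Node ids are store-assigned monotonically increasing integers, stable
  within a session, not across re-imports. Persistence is one JSON file
  per store; indices are rebuilt on load. Single-writer assumption, no
  transactions.
* Re-adding an edge of an existing type between the same nodes is
  idempotent (attributes refreshed); parallel edges of different types
  coexist. Self-edges are allowed and flagged by the validator.
* Degenerate inputs: empty label sets, unknown endpoints, invalid hop
  bounds, empty text queries and cyclic `isA` hierarchies raise typed
  errors; unparseable resource URIs pass through verbatim with a
  warning so odd annotations stay queryable.
* Ties everywhere break lexicographically (species ranking by name,
  search results by URI, best twin counterpart by name) to keep results
  deterministic.
* Problem sizes in the test suite and acceptance script: exhaustive
  pattern-matcher checks on 50 random graphs of ≤ 40 nodes, closure
  checks on 200-node random DAGs, round-trip checks over 100 synthetic
  models, twin-matching on a controlled 15-pair + 5-decoy construction.
  These sizes make the exhaustive oracles exact yet fast.

## Known limitations

* SBML package extensions (comp, fbc) are ignored with a warning; unit
  declarations are skipped.
* CellML 1.1 imports/encapsulation are flattened to component lists;
  CellML ≥ 1.2 is rejected.
* Only `isA` ontology relations are stored; cross-ontology references
  are dropped (and counted).
* The XPath subset for observation targets covers id/name predicates
  only.
* Cross-format linking asserts similarity, not equality, of entities —
  an `IS_SIMILAR_TO` edge is a scored hypothesis, not a merge
  instruction.
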