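# Methods

## The connectivity model and its assumptions

A neuron population is a theoretical grouping of neurons sharing
phenotypic properties that together realize one region-to-region
connection: somata in *A*, axon terminals (or sensory terminals) in *B*,
axon segments in *C*.  The model deliberately does **not** distinguish
whether a population reaching several targets does so via branching axons
or via distinct sub-populations; multiple soma locations mean one
population with distributed origins.  Dendrite-level synaptic circuitry is
out of scope: forward connections indicate that two populations act in
concert across a ganglionic synapse, not a reconstructed synaptic wiring
diagram.  Laterality is carried in entity labels and alert notes only;
there are no left/right logical axioms.

Hard validity requires at least one origin and one destination per
population and forbids self-forward-connections.  Consistency between the
partial-order tree and the location sets is a *warning*, not an error: the
tree and the per-role sets are parallel encodings with no hard
consistency rule, so a node appearing in the path but in no location set
flags probable curation drift without blocking serialization-independent
workflows.

## Dialects

**Axiom dialect.**  Each population is an `owl:Class` whose
`owl:equivalentClass` is the intersection of: a base-class marker
(`ilxtr:NeuronSparcNlp` for literature-derived populations,
`ilxtr:NeuronApinatSimple` for expert-contributed circuit models), taxon
restrictions, sex restriction plus an `owl:complementOf` negating the
opposite sex, phenotype restrictions, one nested
`<role> some ('part of' some <location>)` restriction per (role,
location), and forward-connection restrictions.  Member order inside the
intersection is canonicalized (marker, taxa, sex, phenotypes, then roles
in soma → dendrite → axon → sensory-course → terminals order, CURIEs
sorted within a group) so identical input yields byte-identical Turtle.
The axonal course is a nested RDF collection under
`ilxtr:neuronPartialOrder`: first element the node (literal `"blank"` only
at the root), remaining elements child subtrees.  Sex negation is
serialized as an OWL complement wrapping the opposite-sex restriction —
the one standard RDF rendering of a "not (...)" class expression — and the
reader accepts only that form.  The reader tolerates two documented
deviations: a locational filler missing its part-of wrapper (captured,
with a dialect warning) and taxon/sex fillers wrapped like locations.

**Shortcut dialect.**  One flat triple per (role, location) via the
role's shortcut predicate, plus `hasInstanceInTaxon`, `hasBiologicalSex`
and a package-defined `hasExcludedBiologicalSex` triple for the negated
sex (the flat dialect needs closed-world sex to be expressible without
class expressions), `hasNeuronalPhenotype` / circuit- and functional-role
predicates, `hasForwardConnection`, and `hasConnectedLocation`
materialized to the union of every role's locations.  `hasConnectedLocation`
is asserted rather than implied at query time — an interpretation chosen
so perturbation queries run on any plain triple store.  Pathway adjacency
is materialized as reified edge records (`edgeFrom` / `edgeTo` /
`isConnectedBy`): the edge-annotated `hasNextNode` pattern assumes
edge-property support, and reification keeps the adjacency queryable on
plain-RDF backends.  Interior nodes shared across branches merge by CURIE,
so the four branch copies of a shared nerve yield one edge per distinct
(from, to) pair.

Placeholder predicate names are used where only the predicate's role, not
its IRI, is publicly documented: the axon-course-of-a-sensory-process OWL
property (`hasAxonToSensoryTerminalIn`; its shortcut form
`hasAxonToSensoryTerminal` is documented), and the circuit-role /
functional-role properties (`hasCircuitRolePhenotype`,
`hasFunctionalCircuitRolePhenotype`).  `hasAnatomicalSystemPhenotype`
(axiom side) and `hasNeuronalPhenotype` (shortcut side) are treated as the
same dimension.  The part-of relation is accepted under both spellings
(`partOf:`, i.e. BFO 0000050, and `ilxtr:isPartOf`) and loaded into one
relation.

## Closures and queries

All closures are reflexive-transitive (`*`-path semantics; the start node
is always included) and visited-set guarded, so cyclic — i.e. corrupt —
edge sets cannot hang them.  `suppliesTo` is a third anatomical relation
edge type (a structure supplying an organ), loaded like part-of and used
only where the circuit query scopes end organs.

* **Organ termination** scopes the organ by part-of closure only, and by
  default requires the via to be nerve-like (subclass closure reaching a
  class labeled "nerve", "nerve plexus" or "nerve fiber"); dropping that
  requirement yields a superset.
* **Nerve routing** scopes the nerve by subclass ∪ part-of closure, so
  partonomic branches count.
* **Perturbation** uses connected locations (all roles) of every
  population touching the structure, excluding the structure itself.
* **Innervation circuit** selects phenotype-matching populations whose
  terminals reach the organ via part-of ∪ supplies-to closure, closes over
  reflexive-transitive forward-connection *predecessors* (the relation is
  directed pre→post and deliberately not reciprocal; predecessors come
  from an inverted index, never asserted inverse triples), and emits one
  row per adjacency hop.  A hop's end node is a synapse iff it is an
  axon-terminal location of its own population *and* a soma location of a
  directly forward-connected population.

Label matching everywhere is exact lowercase-folded string equality over
labels and synonyms — no stemming or fuzzy matching.  Result ordering
follows (population, origin, destination, via) with CURIE-lexicographic
tie-breaks, so CSV outputs are stable across runs.

Phenotype summaries report population counts per dimension.  Species
counts are non-exclusive and "Unassigned" counts empty species sets;
locational rows count populations having at least one location in the
role (the presence reading — a per-location-pair reading is also coherent,
but presence is what the summary's population semantics calls for).  The
autonomic dimension uses coarse subdivision buckets, while the circuit
query filters on exact phenotype labels ("Sympathetic Post-Ganglionic
phenotype"); both granularities are exposed.

Sex filtering is closed-world (a female-specific population never appears
under a male filter; populations without sex axioms appear under both);
species filtering is open-world (an empty species set matches only the
"unassigned"/"mammalian" filter, never a named taxon).

## Fixtures and the synthetic generator

The bundled fixtures encode the worked circuits at their published scale:
the branching lumbar pathway with its 4-soma partial order, the ovarian
circuit (two somata, three chain terminals — the wording "three locations"
governs the count even though a T12–L1 span could be read as more
segments), the salivary pathway with its fixed facial → greater petrosal →
vidian nerve order, and two toy graphs for organ- and nerve-scoped
queries.  The forward-connection target of the lumbar population is a
declared *stub* (id + label, no locational content): modeling it as a full
population would add its locations to the perturbation footprint and
contradict the published worked answer.  CURIEs are the real UBERON ids
where publicly printed; everything else is minted in the ILX namespace and
marked synthetic (non-authoritative).

The generator emulates the knowledge base's structure: a partonomy of end
organs with parts (default depth 3), a nerve/nerve-plexus/nerve-fiber
hierarchy with partonomic branches, autonomic ganglia, spinal segments as
origins, and populations with per-role locations, linear partial orders,
and annotation rates.  Defaults — 20 populations over ~80 entities, 45%
sympathetic / 30% parasympathetic / 5% enteric, 18% female- and 8%
male-specific, 65% species-annotated, 3 planted pre→post circuits —
reflect the phenotype mix of a curated autonomic knowledge base, where
autonomic subdivisions dominate, females are over-represented through the
reproductive-system models, and roughly a third of populations lack an
explicit species.  Circuits are planted on reserved organs so that exact
recovery is well-defined; every planted fact goes into the ground-truth
ledger, and the test contract is that the four queries recover the ledger
exactly.  The same (config, seed) yields byte-identical serializations.

What the generator does *not* emulate: the real partonomy's depth and
fan-out irregularity, populations with multiple terminals or convergent
branching paths (random populations in the round-trip tests do cover
multiple somata/terminals), curation noise (dangling CURIEs, label
variants), and the real release's scale.  Green tests therefore
demonstrate correctness of the machinery on conforming graphs, not
robustness to the full messiness of curated data.

## Numerical and procedural choices

* Deterministic serialization comes from canonical ordering plus Turtle
  serialization of a graph built in sorted order; blank nodes are only
  ever referenced once, so no generated labels leak into the output.
* The dialect-equivalence check is dual-route: one leg walks raw
  equivalent-class axioms in the serialized document, the other the flat
  shortcut triples; neither goes through the reconstructed domain objects.
* Closure correctness is checked against a brute-force fixpoint oracle on
  random graphs up to 200 entities.
* Problem sizes in the test suite and acceptance script (50 seeded graphs
  of 8 populations for dialect equivalence, 100 random populations for
  round-trip identity, 10 runs of 12 populations / 3 circuits for ledger
  recovery) were chosen as the smallest scales at which every feature
  combination appears; the checks are exact, so larger sizes add coverage
  only marginally.
* Degenerate inputs: empty graphs produce empty query results and all-zero
  summaries; a population without a partial order contributes no adjacency
  edges and is flagged in the transform report (not fatal); unresolvable
  query labels raise lookup errors rather than returning empty results, so
  typos are not silently confused with negative answers.

## Known limitations

* No OWL-DL reasoning or classification: the shortcut layer exists
  precisely to avoid it, and this package materializes natively rather
  than via SPARQL CONSTRUCT.
* The reverse transformation (shortcut → axiom dialect) is limited to what
  the flat triples preserve: partial-order *trees* are not reconstructed
  from adjacency edges.
* Molecular/morphological phenotype dimensions beyond the subset above,
  probabilistic/confidence annotations, and statement-level provenance are
  not modeled.
* The release benchmark needs the pinned public release downloaded once;
  nothing in it can be bundled here.
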