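"""Shortcut-relation materialization (the "simple" dialect).

The axiom dialect is faithful but painful to query: every location sits two
restriction hops deep inside an equivalent-class intersection.  This module
flattens each population into one shortcut triple per (role, location) pair
plus flat triples for taxa, sex (with an explicit excluded-sex triple for
the negated sex), phenotypes and forward connections, materializes
``hasConnectedLocation`` to the union of all location sets, and derives
pairwise adjacency edges from each partial-order tree.

Adjacency edges are the plain-RDF rendering of the edge-annotated
``hasNextNode`` pattern: each parent→child pair in a tree becomes a reified
edge node carrying ``edgeFrom`` / ``edgeTo`` / ``isConnectedBy`` so the
pathway adjacency stays queryable on backends without edge-property
support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from .model import (
    AnatomicalEntity,
    Citation,
    NeuronPopulation,
    PartialOrderTree,
    PhenotypeAnnotation,
    Provenance,
    SexAssertion,
    SpeciesAssertion,
)
from .owl_io import ILXTR_NS, PART_OF, _NON_POPULATION_PREFIXES, DialectError
from .store import KnowledgeGraph, Triple
from .vocab import (
    ANS_BY_CURIE,
    CIRCUIT_BY_CURIE,
    COMMON_TAXA,
    FUNCTIONAL_BY_CURIE,
    ILXTR,
    MARKER_EXPERT,
    MARKER_LITERATURE,
    P_ALERT_NOTE,
    P_ANS_SIMPLE,
    P_CITATION,
    P_CIRCUIT_ROLE,
    P_CONNECTED,
    P_CONNECTED_BY,
    P_EDGE_FROM,
    P_EDGE_TO,
    P_EXCLUDED_SEX,
    P_FORWARD_SIMPLE,
    P_FUNCTIONAL_ROLE,
    P_IS_PART_OF,
    P_SEX,
    P_SUPPLIES_TO,
    P_TAXON,
    C_PATH_EDGE,
    ROLE_ORDER,
    SEX_BY_CURIE,
    SIMPLE_PREDICATE_TO_ROLE,
    Curie,
    LocationRole,
    PrefixRegistry,
)
from .model import SourceKind

#: (OWL property -> simple predicate) shortcut table.  Total over the
#: location roles and bijective on them; the remaining predicates either
#: rename (forward connection, neuronal phenotype) or pass through.
SHORTCUT_MAPPING: dict[str, str] = {
    **{role.owl_property: role.simple_predicate for role in LocationRole},
    "hasForwardConnectionPhenotype": P_FORWARD_SIMPLE,
    "hasAnatomicalSystemPhenotype": P_ANS_SIMPLE,
    "hasInstanceInTaxon": P_TAXON,
    "hasBiologicalSex": P_SEX,
}


@dataclass(frozen=True, order=True)
class AdjacencyEdge:
    """One parent→child hop of a population's axonal course."""

    from_loc: Curie
    to_loc: Curie
    population: Curie


def partial_order_to_adjacency(
    path: PartialOrderTree, population: Curie
) -> list[AdjacencyEdge]:
    """Pairwise (from, to) hops of a partial-order tree, in document order.

    The blank root contributes no edges.  Structures shared across branches
    (a nerve appearing on several soma branches) are merged by CURIE, so
    duplicate (from, to) pairs collapse to one edge.
    """
    edges: list[AdjacencyEdge] = []
    seen: set[tuple[Curie, Curie]] = set()

    def walk(tree: PartialOrderTree) -> None:
        for child in tree.children:
            if isinstance(tree.node, Curie):
                key = (tree.node, child.node)
                if key not in seen:
                    seen.add(key)
                    edges.append(AdjacencyEdge(tree.node, child.node, population))
            walk(child)

    walk(path)
    return edges


@dataclass
class TransformReport:
    """Non-fatal notes from a materialization run."""

    missing_partial_order: list[Curie] = field(default_factory=list)


def materialize_triples(kg: KnowledgeGraph) -> list[Triple]:
    """The flat shortcut triples for every population in the graph."""
    triples: list[Triple] = []
    for pop_id in sorted(kg.populations, key=lambda c: c.render()):
        triples.extend(materialize_triples_for(kg.populations[pop_id]))
    return triples


def to_simple_graph(
    owl_graph: KnowledgeGraph, report: Optional[TransformReport] = None
) -> KnowledgeGraph:
    """Materialize the shortcut representation of an axiom-level graph.

    Idempotent: materializing an already-simple graph reproduces it.  A
    population lacking a partial order contributes no adjacency edges; it
    is flagged in the run report, not fatal.
    """
    report = report if report is not None else TransformReport()
    adjacency: dict[Curie, tuple] = {}
    for pop_id in sorted(owl_graph.populations, key=lambda c: c.render()):
        pop = owl_graph.populations[pop_id]
        if pop_id in owl_graph.adjacency:
            adjacency[pop_id] = tuple(owl_graph.adjacency[pop_id])
        elif pop.path is not None:
            adjacency[pop_id] = tuple(partial_order_to_adjacency(pop.path, pop_id))
        else:
            report.missing_partial_order.append(pop_id)

    simple = KnowledgeGraph(
        entities=dict(owl_graph.entities),
        populations=dict(owl_graph.populations),
        population_stubs=dict(owl_graph.population_stubs),
        supplies_to=dict(owl_graph.supplies_to),
        prefixes=owl_graph.prefixes,
        dialect="simple",
        adjacency=adjacency,
        term_labels=dict(owl_graph.term_labels),
    )
    return simple


def ensure_simple(graph: KnowledgeGraph) -> KnowledgeGraph:
    return graph if graph.dialect == "simple" else to_simple_graph(graph)


# ------------------------------------------------------------- Turtle I/O

def write_simple_ttl(kg: KnowledgeGraph) -> str:
    """Serialize the simple dialect as Turtle (deterministic)."""
    simple = ensure_simple(kg)
    registry = simple.prefixes
    g = Graph()
    for prefix, base in registry.items():
        g.bind(prefix, Namespace(base), override=True)

    def expand(curie: Curie) -> URIRef:
        return URIRef(registry.expand(curie))

    for curie in sorted(simple.entities):
        ent = simple.entities[curie]
        s = expand(curie)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(ent.label)))
        for syn in sorted(ent.synonyms):
            g.add((s, SKOS.altLabel, Literal(syn)))
        for parent in sorted(ent.part_of):
            g.add((s, ILXTR_NS[P_IS_PART_OF], expand(parent)))
        for parent in sorted(ent.subclass_of):
            g.add((s, RDFS.subClassOf, expand(parent)))
    for source in sorted(simple.supplies_to):
        for organ in sorted(simple.supplies_to[source]):
            g.add((expand(source), ILXTR_NS[P_SUPPLIES_TO], expand(organ)))

    for stub_id in sorted(simple.population_stubs):
        s = expand(stub_id)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(simple.population_stubs[stub_id])))

    value_curies: set[Curie] = set()
    for pop_id in sorted(simple.populations, key=lambda c: c.render()):
        pop = simple.populations[pop_id]
        s = expand(pop_id)
        marker = (
            MARKER_EXPERT
            if pop.provenance.source_kind is SourceKind.EXPERT_MODEL
            else MARKER_LITERATURE
        )
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.subClassOf, expand(marker)))
        g.add((s, RDFS.label, Literal(pop.label)))
        if pop.pref_label:
            g.add((s, SKOS.prefLabel, Literal(pop.pref_label)))
        for note in pop.provenance.alert_notes:
            g.add((s, ILXTR_NS[P_ALERT_NOTE], Literal(note)))
        for citation in sorted(pop.provenance.citations):
            g.add((s, ILXTR_NS[P_CITATION], Literal(citation.render())))
        for triple in materialize_triples_for(pop):
            g.add((s, ILXTR_NS[triple.predicate.local_id], expand(triple.object)))
            if triple.predicate.local_id in (
                P_TAXON, P_SEX, P_EXCLUDED_SEX, P_ANS_SIMPLE, P_CIRCUIT_ROLE, P_FUNCTIONAL_ROLE
            ):
                value_curies.add(triple.object)
        for edge in simple.adjacency.get(pop_id, ()):
            e = BNode()
            g.add((e, RDF.type, ILXTR_NS[C_PATH_EDGE]))
            g.add((e, ILXTR_NS[P_EDGE_FROM], expand(edge.from_loc)))
            g.add((e, ILXTR_NS[P_EDGE_TO], expand(edge.to_loc)))
            g.add((e, ILXTR_NS[P_CONNECTED_BY], s))

    for value in sorted(value_curies):
        label = None
        if value in ANS_BY_CURIE:
            label = ANS_BY_CURIE[value].label
        elif value in CIRCUIT_BY_CURIE:
            label = CIRCUIT_BY_CURIE[value].label
        elif value in FUNCTIONAL_BY_CURIE:
            label = FUNCTIONAL_BY_CURIE[value].label
        elif value in SEX_BY_CURIE:
            label = SEX_BY_CURIE[value].label
        elif value.render() in COMMON_TAXA:
            label = COMMON_TAXA[value.render()]
        if label is not None:
            g.add((expand(value), RDFS.label, Literal(label)))

    return g.serialize(format="turtle")


def materialize_triples_for(pop: NeuronPopulation) -> list[Triple]:
    """Shortcut triples of a single population (object CURIEs only)."""
    ilxtr = lambda name: Curie("ilxtr", name)  # noqa: E731
    triples: list[Triple] = []
    for role in ROLE_ORDER:
        for loc in sorted(pop.locs(role)):
            triples.append(Triple(pop.id, ilxtr(role.simple_predicate), loc))
    for loc in sorted(pop.all_locations):
        triples.append(Triple(pop.id, ilxtr(P_CONNECTED), loc))
    for taxon in sorted(pop.species.taxa):
        triples.append(Triple(pop.id, ilxtr(P_TAXON), taxon))
    if pop.sex.sex is not None:
        triples.append(Triple(pop.id, ilxtr(P_SEX), pop.sex.sex.curie))
        triples.append(Triple(pop.id, ilxtr(P_EXCLUDED_SEX), pop.sex.sex.opposite.curie))
    if pop.phenotypes.ans is not None:
        triples.append(Triple(pop.id, ilxtr(P_ANS_SIMPLE), pop.phenotypes.ans.curie))
    if pop.phenotypes.circuit_role is not None:
        triples.append(Triple(pop.id, ilxtr(P_CIRCUIT_ROLE), pop.phenotypes.circuit_role.curie))
    if pop.phenotypes.functional_role is not None:
        triples.append(
            Triple(pop.id, ilxtr(P_FUNCTIONAL_ROLE), pop.phenotypes.functional_role.curie)
        )
    for target in sorted(pop.forward_connections):
        triples.append(Triple(pop.id, ilxtr(P_FORWARD_SIMPLE), target))
    return triples


def read_simple_ttl(text: str, registry: Optional[PrefixRegistry] = None) -> KnowledgeGraph:
    """Load a simple-dialect Turtle document into a knowledge graph.

    This reader keys purely on the shortcut predicates, so any conforming
    flat-triple distribution loads directly.  Populations reconstructed
    from flat triples carry no partial-order tree; their pathway adjacency
    comes from the reified edge records when present.
    """
    g = Graph()
    g.parse(data=text, format="turtle")

    registry = registry or PrefixRegistry()
    for prefix, ns in g.namespaces():
        if prefix and prefix not in registry:
            registry.register(prefix, str(ns))

    def compact(iri) -> Optional[Curie]:
        return registry.compact(str(iri))

    kg = KnowledgeGraph(prefixes=registry, dialect="simple")

    # entities
    for s in set(g.subjects(RDFS.label, None)):
        if not isinstance(s, URIRef):
            continue
        c = compact(s)
        if c is None or not c.is_anatomical:
            continue
        part_of = set()
        for pred in (ILXTR_NS[P_IS_PART_OF], PART_OF):
            part_of |= {compact(o) for o in g.objects(s, pred) if isinstance(o, URIRef)}
        subclass_of = {
            compact(o)
            for o in g.objects(s, RDFS.subClassOf)
            if isinstance(o, URIRef) and compact(o) is not None and compact(o).is_anatomical
        }
        kg.add_entity(
            AnatomicalEntity(
                curie=c,
                label=str(g.value(s, RDFS.label)),
                synonyms=frozenset(str(o) for o in g.objects(s, SKOS.altLabel)),
                part_of=frozenset(p for p in part_of if p is not None),
                subclass_of=frozenset(p for p in subclass_of if p is not None),
            )
        )
        supplies = frozenset(
            compact(o) for o in g.objects(s, ILXTR_NS[P_SUPPLIES_TO]) if isinstance(o, URIRef)
        )
        if supplies:
            kg.supplies_to[c] = supplies

    # populations: any subject with at least one shortcut predicate
    pop_subjects: set[URIRef] = set()
    for name in list(SIMPLE_PREDICATE_TO_ROLE) + [P_CONNECTED, P_FORWARD_SIMPLE, P_ANS_SIMPLE]:
        pop_subjects |= {
            s for s in g.subjects(ILXTR_NS[name], None) if isinstance(s, URIRef)
        }

    for s in sorted(pop_subjects, key=str):
        pop_id = compact(s)
        if pop_id is None:
            raise DialectError(f"population IRI outside every registered namespace: {s}")
        locations = {}
        for name, role in SIMPLE_PREDICATE_TO_ROLE.items():
            locs = frozenset(
                compact(o) for o in g.objects(s, ILXTR_NS[name]) if isinstance(o, URIRef)
            )
            if locs:
                locations[role] = locs
        taxa = frozenset(
            compact(o) for o in g.objects(s, ILXTR_NS[P_TAXON]) if isinstance(o, URIRef)
        )
        sex_term = g.value(s, ILXTR_NS[P_SEX])
        sex = SEX_BY_CURIE.get(compact(sex_term)) if isinstance(sex_term, URIRef) else None
        ans = None
        for o in g.objects(s, ILXTR_NS[P_ANS_SIMPLE]):
            if isinstance(o, URIRef):
                ans = ANS_BY_CURIE.get(compact(o)) or ans
        circuit_role = None
        for o in g.objects(s, ILXTR_NS[P_CIRCUIT_ROLE]):
            if isinstance(o, URIRef):
                circuit_role = CIRCUIT_BY_CURIE.get(compact(o)) or circuit_role
        functional_role = None
        for o in g.objects(s, ILXTR_NS[P_FUNCTIONAL_ROLE]):
            if isinstance(o, URIRef):
                functional_role = FUNCTIONAL_BY_CURIE.get(compact(o)) or functional_role
        forward = frozenset(
            compact(o) for o in g.objects(s, ILXTR_NS[P_FORWARD_SIMPLE]) if isinstance(o, URIRef)
        )
        source_kind = SourceKind.LITERATURE
        for o in g.objects(s, RDFS.subClassOf):
            if isinstance(o, URIRef) and compact(o) == MARKER_EXPERT:
                source_kind = SourceKind.EXPERT_MODEL
        label_term = g.value(s, RDFS.label)
        pref_term = g.value(s, SKOS.prefLabel)
        notes = tuple(sorted(str(o) for o in g.objects(s, ILXTR_NS[P_ALERT_NOTE])))
        citations = frozenset(
            Citation.parse(str(o)) for o in g.objects(s, ILXTR_NS[P_CITATION])
        )
        kg.add_population(
            NeuronPopulation(
                id=pop_id,
                label=str(label_term) if label_term is not None else pop_id.render(),
                pref_label=str(pref_term) if pref_term is not None else "",
                locations=locations,
                path=None,
                phenotypes=PhenotypeAnnotation(
                    ans=ans, circuit_role=circuit_role, functional_role=functional_role
                ),
                species=SpeciesAssertion(taxa),
                sex=SexAssertion(sex),
                forward_connections=forward,
                provenance=Provenance(
                    citations=citations, alert_notes=notes, source_kind=source_kind
                ),
            )
        )

    # reified adjacency edges
    adjacency: dict[Curie, list[AdjacencyEdge]] = {}
    for e in sorted(set(g.subjects(ILXTR_NS[P_EDGE_FROM], None)), key=str):
        from_term = g.value(e, ILXTR_NS[P_EDGE_FROM])
        to_term = g.value(e, ILXTR_NS[P_EDGE_TO])
        pop_term = g.value(e, ILXTR_NS[P_CONNECTED_BY])
        if from_term is None or to_term is None or pop_term is None:
            raise DialectError(f"incomplete adjacency edge record {e}")
        pop_c = compact(pop_term)
        edge = AdjacencyEdge(compact(from_term), compact(to_term), pop_c)
        adjacency.setdefault(pop_c, []).append(edge)
    for pop_c, edges in adjacency.items():
        kg.adjacency[pop_c] = tuple(sorted(edges))

    # stubs: declared classes under population namespaces with no content
    for s in set(g.subjects(RDF.type, OWL.Class)):
        if not isinstance(s, URIRef) or s in pop_subjects:
            continue
        c = compact(s)
        if c is None or c.is_anatomical or c.prefix in _NON_POPULATION_PREFIXES:
            continue
        label_term = g.value(s, RDFS.label)
        kg.add_stub(c, str(label_term) if label_term is not None else c.render())

    for s in set(g.subjects(RDFS.label, None)):
        if not isinstance(s, URIRef):
            continue
        c = compact(s)
        if (
            c is not None
            and not c.is_anatomical
            and c not in kg.populations
            and c not in kg.population_stubs
        ):
            kg.term_labels[c] = str(g.value(s, RDFS.label))

    return kg


# ------------------------------------------------- dual-route query check

def origins_destinations_owl_pattern(owl_ttl: str) -> list[tuple[str, str, str]]:
    """Origin/destination listing straight off the axiom-dialect document.

    Walks the raw ``owl:equivalentClass`` / ``owl:intersectionOf`` /
    nested-restriction graph pattern, never the reconstructed domain
    objects, so it can serve as one leg of the dialect-equivalence check.
    """
    g = Graph()
    g.parse(data=owl_ttl, format="turtle")
    soma_prop = ILXTR_NS[LocationRole.SOMA.owl_property]
    terminal_props = {
        ILXTR_NS[LocationRole.AXON_TERMINAL.owl_property],
        ILXTR_NS[LocationRole.SENSORY_TERMINAL.owl_property],
    }
    rows: set[tuple[str, str, str]] = set()
    for neuron, eq in g.subject_objects(OWL.equivalentClass):
        head = g.value(eq, OWL.intersectionOf)
        if head is None:
            continue
        origins: set[str] = set()
        destinations: set[str] = set()
        node = head
        while node is not None and node != RDF.nil:
            member = g.value(node, RDF.first)
            prop = g.value(member, OWL.onProperty) if member is not None else None
            filler = g.value(member, OWL.someValuesFrom) if member is not None else None
            if prop is not None and filler is not None:
                inner = filler
                if not isinstance(filler, URIRef):
                    inner = g.value(filler, OWL.someValuesFrom)
                if isinstance(inner, URIRef):
                    if prop == soma_prop:
                        origins.add(str(inner))
                    elif prop in terminal_props:
                        destinations.add(str(inner))
            node = g.value(node, RDF.rest)
        for a in origins:
            for b in destinations:
                rows.add((str(neuron), a, b))
    return sorted(rows)


def origins_destinations_simple_pattern(simple_ttl: str) -> list[tuple[str, str, str]]:
    """The same listing off the flat shortcut predicates."""
    g = Graph()
    g.parse(data=simple_ttl, format="turtle")
    soma = ILXTR_NS[LocationRole.SOMA.simple_predicate]
    terminals = (
        ILXTR_NS[LocationRole.AXON_TERMINAL.simple_predicate],
        ILXTR_NS[LocationRole.SENSORY_TERMINAL.simple_predicate],
    )
    rows: set[tuple[str, str, str]] = set()
    for neuron, a in g.subject_objects(soma):
        for pred in terminals:
            for b in g.objects(neuron, pred):
                rows.add((str(neuron), str(a), str(b)))
    return sorted(rows)
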