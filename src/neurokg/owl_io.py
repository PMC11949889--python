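"""Read and write the OWL/Turtle axiom dialect.

Each neuron population is serialized as an ``owl:Class`` carrying
``rdfs:label`` / ``skos:prefLabel`` annotations and an
``owl:equivalentClass`` axiom whose filler is the intersection of

* a base class marker (``ilxtr:NeuronSparcNlp`` for literature-extracted
  populations, ``ilxtr:NeuronApinatSimple`` for expert-contributed models),
* one ``hasInstanceInTaxon some <taxon>`` restriction per observed taxon
  (none when the species set is empty — open world),
* when sex-specific, a ``hasBiologicalSex some <sex>`` restriction plus an
  ``owl:complementOf`` member negating the opposite sex (closed world),
* phenotype restrictions (autonomic subdivision, circuit role, functional
  role),
* one nested restriction per (role, location) pair — every locational
  filler is wrapped in a ``'part of' some <location>`` restriction,
* one ``hasForwardConnectionPhenotype some <population>`` restriction per
  forward connection.

The axonal course is serialized separately as the object of
``ilxtr:neuronPartialOrder``: a nested RDF collection whose first element
is the node (the literal ``"blank"`` at the root, a CURIE elsewhere) and
whose remaining elements are child subtrees.

Member order inside the intersection is canonicalized (marker, taxa, sex,
phenotypes, soma, dendrite, axon, terminals, forward connections; CURIE
order within a group), so identical input produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

from .model import (
    BLANK,
    AnatomicalEntity,
    Citation,
    NeuronPopulation,
    PartialOrderTree,
    PhenotypeAnnotation,
    Provenance,
    SexAssertion,
    SpeciesAssertion,
    TreeError,
    hard_errors,
    validate_population,
)
from .vocab import (
    ANS_BY_CURIE,
    CIRCUIT_BY_CURIE,
    COMMON_TAXA,
    FUNCTIONAL_BY_CURIE,
    ILXTR,
    MARKER_EXPERT,
    MARKER_LITERATURE,
    OWL_PROPERTY_TO_ROLE,
    PARTOF_IRI,
    P_ALERT_NOTE,
    P_ANS_OWL,
    P_ANS_SIMPLE,
    P_CITATION,
    P_CIRCUIT_ROLE,
    P_FORWARD_OWL,
    P_FUNCTIONAL_ROLE,
    P_IS_PART_OF,
    P_PARTIAL_ORDER,
    P_SEX,
    P_SUPPLIES_TO,
    P_TAXON,
    ROLE_ORDER,
    Curie,
    PrefixRegistry,
    SEX_BY_CURIE,
)
from .model import SourceKind

ILXTR_NS = Namespace(ILXTR)
PART_OF = URIRef(PARTOF_IRI)

#: Prefixes that never denote population namespaces when reading.
_NON_POPULATION_PREFIXES = frozenset(
    {"UBERON", "ILX", "ilxtr", "NCBITaxon", "PATO", "partOf", "rdf", "rdfs", "owl", "skos"}
)


class DialectError(ValueError):
    """The document is valid Turtle but violates the axiom dialect."""


@dataclass
class ReadResult:
    """Parsed content of a dialect document.

    Iterates as ``(populations, entities)`` so callers can unpack the two
    primary products while still reaching stubs, supplies-to edges and
    dialect warnings through attributes.
    """

    populations: list[NeuronPopulation] = field(default_factory=list)
    entities: list[AnatomicalEntity] = field(default_factory=list)
    stubs: dict[Curie, str] = field(default_factory=dict)
    supplies_to: dict[Curie, frozenset[Curie]] = field(default_factory=dict)
    term_labels: dict[Curie, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    prefixes: Optional[PrefixRegistry] = None

    def __iter__(self):
        return iter((self.populations, self.entities))


# ----------------------------------------------------------------- writing

def _rdf_list(g: Graph, items: Sequence) -> Union[BNode, URIRef]:
    if not items:
        return RDF.nil
    head = BNode()
    node = head
    for i, item in enumerate(items):
        g.add((node, RDF.first, item))
        if i == len(items) - 1:
            g.add((node, RDF.rest, RDF.nil))
        else:
            nxt = BNode()
            g.add((node, RDF.rest, nxt))
            node = nxt
    return head


def _restriction(g: Graph, prop: URIRef, filler) -> BNode:
    b = BNode()
    g.add((b, RDF.type, OWL.Restriction))
    g.add((b, OWL.onProperty, prop))
    g.add((b, OWL.someValuesFrom, filler))
    return b


def _part_of_restriction(g: Graph, location: URIRef) -> BNode:
    return _restriction(g, PART_OF, location)


def _tree_to_collection(g: Graph, tree: PartialOrderTree, expand) -> BNode:
    head = Literal(BLANK) if tree.is_root else expand(tree.node)
    items = [head] + [_tree_to_collection(g, child, expand) for child in tree.children]
    return _rdf_list(g, items)


def write_ttl(
    pops: Iterable[NeuronPopulation],
    entities: Iterable[AnatomicalEntity],
    stubs: Optional[dict[Curie, str]] = None,
    supplies_to: Optional[dict[Curie, frozenset[Curie]]] = None,
    registry: Optional[PrefixRegistry] = None,
    emit_label_comments: bool = False,
) -> str:
    """Serialize populations and entities to the OWL axiom dialect.

    Refuses (raising :class:`ValueError` with the validation report) if any
    population fails hard validation.  Output is deterministic for
    identical input.  With ``emit_label_comments`` a human-readable CURIE →
    label index is appended as trailing Turtle comments (non-semantic).
    """
    pops = sorted(pops, key=lambda p: p.id.render())
    entities = sorted(entities, key=lambda e: e.curie.render())
    stubs = stubs or {}
    supplies_to = supplies_to or {}
    registry = registry or PrefixRegistry()
    for pop in pops:
        report = hard_errors(validate_population(pop))
        if report:
            raise ValueError(
                f"refusing to serialize invalid population {pop.id}: "
                + "; ".join(i.message for i in report)
            )
        if pop.id.prefix not in registry:
            raise ValueError(f"population prefix {pop.id.prefix!r} not in the prefix registry")

    g = Graph()
    for prefix, base in registry.items():
        g.bind(prefix, Namespace(base), override=True)

    def expand(curie: Curie) -> URIRef:
        return URIRef(registry.expand(curie))

    labels: dict[str, str] = {}

    for ent in entities:
        s = expand(ent.curie)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(ent.label)))
        labels[ent.curie.render()] = ent.label
        for syn in sorted(ent.synonyms):
            g.add((s, SKOS.altLabel, Literal(syn)))
        for parent in sorted(ent.subclass_of):
            g.add((s, RDFS.subClassOf, expand(parent)))
        for parent in sorted(ent.part_of):
            g.add((s, RDFS.subClassOf, _part_of_restriction(g, expand(parent))))

    for source, organs in sorted(supplies_to.items()):
        for organ in sorted(organs):
            g.add((expand(source), ILXTR_NS[P_SUPPLIES_TO], expand(organ)))

    for stub_id, stub_label in sorted(stubs.items()):
        s = expand(stub_id)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(stub_label)))

    emitted_values: set[Curie] = set()

    for pop in pops:
        s = expand(pop.id)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(pop.label)))
        if pop.pref_label:
            g.add((s, SKOS.prefLabel, Literal(pop.pref_label)))
        for note in pop.provenance.alert_notes:
            g.add((s, ILXTR_NS[P_ALERT_NOTE], Literal(note)))
        for citation in sorted(pop.provenance.citations):
            g.add((s, ILXTR_NS[P_CITATION], Literal(citation.render())))

        members: list = []
        marker = (
            MARKER_EXPERT
            if pop.provenance.source_kind is SourceKind.EXPERT_MODEL
            else MARKER_LITERATURE
        )
        members.append(expand(marker))
        for taxon in sorted(pop.species.taxa):
            members.append(_restriction(g, ILXTR_NS[P_TAXON], expand(taxon)))
            emitted_values.add(taxon)
        if pop.sex.sex is not None:
            members.append(_restriction(g, ILXTR_NS[P_SEX], expand(pop.sex.sex.curie)))
            neg = BNode()
            g.add((neg, RDF.type, OWL.Class))
            g.add(
                (
                    neg,
                    OWL.complementOf,
                    _restriction(g, ILXTR_NS[P_SEX], expand(pop.sex.sex.opposite.curie)),
                )
            )
            members.append(neg)
            emitted_values.add(pop.sex.sex.curie)
            emitted_values.add(pop.sex.sex.opposite.curie)
        if pop.phenotypes.ans is not None:
            members.append(
                _restriction(g, ILXTR_NS[P_ANS_OWL], expand(pop.phenotypes.ans.curie))
            )
            emitted_values.add(pop.phenotypes.ans.curie)
        if pop.phenotypes.circuit_role is not None:
            members.append(
                _restriction(g, ILXTR_NS[P_CIRCUIT_ROLE], expand(pop.phenotypes.circuit_role.curie))
            )
            emitted_values.add(pop.phenotypes.circuit_role.curie)
        if pop.phenotypes.functional_role is not None:
            members.append(
                _restriction(
                    g, ILXTR_NS[P_FUNCTIONAL_ROLE], expand(pop.phenotypes.functional_role.curie)
                )
            )
            emitted_values.add(pop.phenotypes.functional_role.curie)
        for role in ROLE_ORDER:
            for loc in sorted(pop.locs(role)):
                members.append(
                    _restriction(
                        g, ILXTR_NS[role.owl_property], _part_of_restriction(g, expand(loc))
                    )
                )
        for target in sorted(pop.forward_connections):
            members.append(_restriction(g, ILXTR_NS[P_FORWARD_OWL], expand(target)))

        eq = BNode()
        g.add((eq, RDF.type, OWL.Class))
        g.add((eq, OWL.intersectionOf, _rdf_list(g, members)))
        g.add((s, OWL.equivalentClass, eq))

        if pop.path is not None:
            g.add((s, ILXTR_NS[P_PARTIAL_ORDER], _tree_to_collection(g, pop.path, expand)))

    # labels for taxa / phenotype values so label-joining queries work
    for value in sorted(emitted_values):
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
            labels[value.render()] = label

    text = g.serialize(format="turtle")
    if emit_label_comments:
        index = "".join(f"# {c}  {label}\n" for c, label in sorted(labels.items()))
        text = text.rstrip("\n") + "\n\n# --- label index ---\n" + index
    return text


# ----------------------------------------------------------------- reading

def _collection_items(g: Graph, head) -> list:
    items = []
    node = head
    seen = set()
    while node != RDF.nil:
        if not isinstance(node, BNode) or node in seen:
            raise TreeError("malformed RDF collection under neuronPartialOrder")
        seen.add(node)
        first = g.value(node, RDF.first)
        rest = g.value(node, RDF.rest)
        if first is None or rest is None:
            raise TreeError("RDF collection node missing rdf:first/rdf:rest")
        items.append(first)
        node = rest
    return items


def _parse_tree(g: Graph, head, compact, at_root: bool) -> PartialOrderTree:
    items = _collection_items(g, head)
    if not items:
        raise TreeError("empty collection in partial-order tree")
    node_term, *child_terms = items
    if isinstance(node_term, Literal):
        if str(node_term) != BLANK or not at_root:
            raise TreeError(f"unexpected literal node {node_term!r} in partial-order tree")
        node: Union[Curie, str] = BLANK
    elif isinstance(node_term, URIRef):
        node = compact(node_term)
    else:
        raise TreeError(f"partial-order node must be a CURIE or 'blank', got {node_term!r}")
    children = tuple(_parse_tree(g, c, compact, at_root=False) for c in child_terms)
    return PartialOrderTree(node, children)


def _local_name(prop: URIRef) -> Optional[str]:
    text = str(prop)
    if text.startswith(ILXTR):
        return text[len(ILXTR):]
    if text == PARTOF_IRI:
        return P_IS_PART_OF
    return None


def read_ttl(text: str, registry: Optional[PrefixRegistry] = None) -> ReadResult:
    """Parse an OWL-dialect document back into populations and entities.

    Structural identity holds round-trip: ``read_ttl(write_ttl(pops,
    entities))`` reconstructs every population field-for-field, including
    nested partial-order trees.  A soma/axon/terminal restriction lacking
    the nested part-of wrapper is tolerated with a dialect warning (the
    location is still captured); an equivalent-class axiom without a base
    class marker is a :class:`DialectError` naming the population IRI.
    """
    g = Graph()
    g.parse(data=text, format="turtle")

    registry = registry or PrefixRegistry()
    for prefix, ns in g.namespaces():
        base = str(ns)
        if prefix and prefix not in registry:
            registry.register(prefix, base)

    result = ReadResult(prefixes=registry)

    def compact(iri: URIRef) -> Curie:
        c = registry.compact(str(iri))
        if c is None:
            raise DialectError(f"IRI outside every registered namespace: {iri}")
        return c

    def _location_filler(filler, pop_iri) -> Curie:
        if isinstance(filler, URIRef):
            result.warnings.append(
                f"{pop_iri}: locational restriction lacks the nested part-of wrapper"
            )
            return compact(filler)
        inner_prop = g.value(filler, OWL.onProperty)
        inner_filler = g.value(filler, OWL.someValuesFrom)
        if inner_prop is None or inner_filler is None or not isinstance(inner_filler, URIRef):
            raise DialectError(f"{pop_iri}: unparseable locational restriction filler")
        if str(inner_prop) not in (PARTOF_IRI, ILXTR + P_IS_PART_OF):
            result.warnings.append(
                f"{pop_iri}: locational wrapper uses unexpected property {inner_prop}"
            )
        return compact(inner_filler)

    def _value_filler(filler, pop_iri) -> Curie:
        # Taxon/sex/phenotype fillers are normally bare IRIs; tolerate a
        # part-of wrapper around them as well.
        if isinstance(filler, URIRef):
            return compact(filler)
        return _location_filler(filler, pop_iri)

    # --- entities ---------------------------------------------------
    entity_subjects = set()
    for s in set(g.subjects(RDFS.label, None)):
        if not isinstance(s, URIRef):
            continue
        c = registry.compact(str(s))
        if c is not None and c.is_anatomical:
            entity_subjects.add((s, c))

    for s, c in sorted(entity_subjects, key=lambda t: t[1].render()):
        label = str(g.value(s, RDFS.label))
        synonyms = frozenset(str(o) for o in g.objects(s, SKOS.altLabel))
        part_of: set[Curie] = set()
        subclass_of: set[Curie] = set()
        for o in g.objects(s, RDFS.subClassOf):
            if isinstance(o, URIRef):
                oc = registry.compact(str(o))
                if oc is not None and oc.is_anatomical:
                    subclass_of.add(oc)
            elif isinstance(o, BNode) and (o, RDF.type, OWL.Restriction) in g:
                prop = g.value(o, OWL.onProperty)
                filler = g.value(o, OWL.someValuesFrom)
                if (
                    prop is not None
                    and str(prop) in (PARTOF_IRI, ILXTR + P_IS_PART_OF)
                    and isinstance(filler, URIRef)
                ):
                    part_of.add(compact(filler))
        # simple-dialect spelling of the same relation is accepted too
        for pred in (PART_OF, ILXTR_NS[P_IS_PART_OF]):
            for o in g.objects(s, pred):
                if isinstance(o, URIRef):
                    part_of.add(compact(o))
        supplies = frozenset(
            compact(o) for o in g.objects(s, ILXTR_NS[P_SUPPLIES_TO]) if isinstance(o, URIRef)
        )
        if supplies:
            result.supplies_to[c] = supplies
        result.entities.append(
            AnatomicalEntity(
                curie=c,
                label=label,
                synonyms=synonyms,
                part_of=frozenset(part_of),
                subclass_of=frozenset(subclass_of),
            )
        )

    # --- populations ------------------------------------------------
    pop_subjects = sorted(
        (s for s in set(g.subjects(OWL.equivalentClass, None)) if isinstance(s, URIRef)),
        key=str,
    )
    for s in pop_subjects:
        pop_id = compact(s)
        eq = g.value(s, OWL.equivalentClass)
        members_head = g.value(eq, OWL.intersectionOf) if eq is not None else None
        if members_head is None:
            raise DialectError(f"population {s} has no owl:intersectionOf equivalent class")
        members = _collection_items(g, members_head)

        source_kind: Optional[SourceKind] = None
        taxa: set[Curie] = set()
        sex_positive = None
        sex_negated = None
        ans = None
        circuit_role = None
        functional_role = None
        locations: dict = {}
        forward: set[Curie] = set()

        for member in members:
            if isinstance(member, URIRef):
                mc = compact(member)
                if mc == MARKER_LITERATURE:
                    source_kind = SourceKind.LITERATURE
                elif mc == MARKER_EXPERT:
                    source_kind = SourceKind.EXPERT_MODEL
                else:
                    result.warnings.append(f"{s}: unrecognized named intersection member {mc}")
                continue
            if (member, OWL.complementOf, None) in g:
                inner = g.value(member, OWL.complementOf)
                prop = g.value(inner, OWL.onProperty)
                filler = g.value(inner, OWL.someValuesFrom)
                if prop is None or _local_name(prop) != P_SEX or not isinstance(filler, URIRef):
                    raise DialectError(f"{s}: unsupported complement member (expected sex negation)")
                sex_negated = SEX_BY_CURIE.get(compact(filler))
                continue
            prop = g.value(member, OWL.onProperty)
            filler = g.value(member, OWL.someValuesFrom)
            if prop is None or filler is None:
                raise DialectError(f"{s}: intersection member is not a someValuesFrom restriction")
            name = _local_name(prop)
            if name in OWL_PROPERTY_TO_ROLE:
                role = OWL_PROPERTY_TO_ROLE[name]
                loc = _location_filler(filler, s)
                locations.setdefault(role, set()).add(loc)
            elif name == P_TAXON:
                taxa.add(_value_filler(filler, s))
            elif name == P_SEX:
                sex_positive = SEX_BY_CURIE.get(_value_filler(filler, s))
            elif name in (P_ANS_OWL, P_ANS_SIMPLE):
                ans = ANS_BY_CURIE.get(_value_filler(filler, s))
            elif name == P_CIRCUIT_ROLE:
                circuit_role = CIRCUIT_BY_CURIE.get(_value_filler(filler, s))
            elif name == P_FUNCTIONAL_ROLE:
                functional_role = FUNCTIONAL_BY_CURIE.get(_value_filler(filler, s))
            elif name == P_FORWARD_OWL:
                forward.add(_value_filler(filler, s))
            else:
                result.warnings.append(f"{s}: unrecognized restriction property {prop}")

        if source_kind is None:
            raise DialectError(f"population {s} lacks a base class marker "
                               f"({MARKER_LITERATURE} or {MARKER_EXPERT})")
        if sex_positive is not None and sex_negated is not None:
            if sex_negated is not sex_positive.opposite:
                raise DialectError(f"{s}: sex negation does not negate the opposite sex")
        if sex_positive is None and sex_negated is not None:
            sex_positive = sex_negated.opposite
            result.warnings.append(f"{s}: sex negation present without a positive sex restriction")

        label_term = g.value(s, RDFS.label)
        pref_term = g.value(s, SKOS.prefLabel)
        notes = tuple(sorted(str(o) for o in g.objects(s, ILXTR_NS[P_ALERT_NOTE])))
        citations = frozenset(
            Citation.parse(str(o)) for o in g.objects(s, ILXTR_NS[P_CITATION])
        )

        path = None
        path_head = g.value(s, ILXTR_NS[P_PARTIAL_ORDER])
        if path_head is not None:
            path = _parse_tree(g, path_head, compact, at_root=True)

        result.populations.append(
            NeuronPopulation(
                id=pop_id,
                label=str(label_term) if label_term is not None else pop_id.render(),
                pref_label=str(pref_term) if pref_term is not None else "",
                locations={r: frozenset(v) for r, v in locations.items()},
                path=path,
                phenotypes=PhenotypeAnnotation(
                    ans=ans, circuit_role=circuit_role, functional_role=functional_role
                ),
                species=SpeciesAssertion(frozenset(taxa)),
                sex=SexAssertion(sex_positive),
                forward_connections=frozenset(forward),
                provenance=Provenance(
                    citations=citations, alert_notes=notes, source_kind=source_kind
                ),
            )
        )

    # --- stubs and term labels --------------------------------------
    pop_ids = {p.id for p in result.populations}
    for s in set(g.subjects(RDF.type, OWL.Class)):
        if not isinstance(s, URIRef):
            continue
        c = registry.compact(str(s))
        if (
            c is None
            or c.is_anatomical
            or c.prefix in _NON_POPULATION_PREFIXES
            or c in pop_ids
        ):
            continue
        label_term = g.value(s, RDFS.label)
        result.stubs[c] = str(label_term) if label_term is not None else c.render()

    for s in set(g.subjects(RDFS.label, None)):
        if not isinstance(s, URIRef):
            continue
        c = registry.compact(str(s))
        if c is not None and not c.is_anatomical and c not in pop_ids and c not in result.stubs:
            result.term_labels[c] = str(g.value(s, RDFS.label))

    result.populations.sort(key=lambda p: p.id.render())
    result.entities.sort(key=lambda e: e.curie.render())
    return result


# ----------------------------------------------------------- KG adapters

def graph_to_owl(kg, emit_label_comments: bool = False) -> str:
    """Serialize a whole knowledge graph to the OWL dialect."""
    return write_ttl(
        kg.populations.values(),
        kg.entities.values(),
        stubs=kg.population_stubs,
        supplies_to=kg.supplies_to,
        registry=kg.prefixes,
        emit_label_comments=emit_label_comments,
    )


def graph_from_owl(text: str, registry: Optional[PrefixRegistry] = None):
    """Parse an OWL-dialect document into a :class:`KnowledgeGraph`."""
    from .store import KnowledgeGraph

    result = read_ttl(text, registry=registry)
    kg = KnowledgeGraph(prefixes=result.prefixes or PrefixRegistry(), dialect="owl")
    for ent in result.entities:
        kg.add_entity(ent)
    for pop in result.populations:
        kg.add_population(pop)
    kg.population_stubs.update(result.stubs)
    kg.supplies_to.update(result.supplies_to)
    kg.term_labels.update(result.term_labels)
    return kg
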