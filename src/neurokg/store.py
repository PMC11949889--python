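"""In-memory knowledge graph with closure and label-resolution services.

The store keeps anatomical entities (with their raw part-of / subclass
edges), full neuron populations, declared-but-unspecified population stubs
(classes that only exist as forward-connection targets), and supplies-to
edges between structures.  On top of that it offers the three services the
competency queries need: reflexive-transitive ancestor closure over a
chosen set of relations, case-insensitive label/synonym resolution, and the
"is this a nerve, nerve plexus or nerve fiber" test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .model import AnatomicalEntity, NeuronPopulation
from .vocab import Curie, NERVE_LIKE_LABELS, COMMON_TAXA, PrefixRegistry

#: Relation names accepted by :meth:`KnowledgeGraph.ancestors`.
RELATIONS = ("part_of", "subclass_of", "supplies_to")


@dataclass(frozen=True)
class Triple:
    """A flat simple-dialect triple (object either CURIE or literal text)."""

    subject: Curie
    predicate: Curie
    object: Union[Curie, str]


class UnknownCurieError(KeyError):
    pass


@dataclass
class KnowledgeGraph:
    """Entities + populations + relation edges, with closure services.

    ``dialect`` records how the graph was produced: ``"owl"`` for graphs
    holding full axiom-level content (partial-order trees on populations)
    and ``"simple"`` for graphs loaded from, or materialized into, the flat
    shortcut-triple dialect (reified adjacency edges in ``adjacency``).
    """

    entities: dict[Curie, AnatomicalEntity] = field(default_factory=dict)
    populations: dict[Curie, NeuronPopulation] = field(default_factory=dict)
    population_stubs: dict[Curie, str] = field(default_factory=dict)
    supplies_to: dict[Curie, frozenset[Curie]] = field(default_factory=dict)
    prefixes: PrefixRegistry = field(default_factory=PrefixRegistry)
    dialect: str = "owl"
    #: Adjacency edges per population, present on simple-dialect graphs.
    adjacency: dict[Curie, tuple] = field(default_factory=dict)
    #: Extra labels for non-anatomical terms (taxa, phenotype values).
    term_labels: dict[Curie, str] = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def add_entity(self, entity: AnatomicalEntity) -> None:
        self.entities[entity.curie] = entity
        self._label_index = None

    def add_population(self, pop: NeuronPopulation) -> None:
        self.populations[pop.id] = pop

    def add_stub(self, curie: Curie, label: str) -> None:
        self.population_stubs[curie] = label

    def add_supplies_to(self, source: Curie, organ: Curie) -> None:
        self.supplies_to[source] = self.supplies_to.get(source, frozenset()) | {organ}

    # -- resolution ---------------------------------------------------
    def knows(self, curie: Curie) -> bool:
        return curie in self.entities

    def knows_population(self, curie: Curie) -> bool:
        return curie in self.populations or curie in self.population_stubs

    @property
    def unresolved(self) -> frozenset[Curie]:
        """CURIEs referenced by population locations that no entity defines."""
        missing: set[Curie] = set()
        for pop in self.populations.values():
            for loc in pop.all_locations:
                if loc not in self.entities:
                    missing.add(loc)
        return frozenset(missing)

    def label_of(self, curie: Curie) -> str:
        ent = self.entities.get(curie)
        if ent is not None:
            return ent.label
        if curie in self.term_labels:
            return self.term_labels[curie]
        if curie in self.populations:
            return self.populations[curie].label
        if curie in self.population_stubs:
            return self.population_stubs[curie]
        return COMMON_TAXA.get(curie.render(), curie.render())

    _label_index = None

    def resolve_label(self, label: str) -> frozenset[Curie]:
        """All entities whose label or a synonym equals ``label``.

        Matching is exact string equality after lowercase folding (no
        stemming, no fuzzy matching); returns the empty set on no match.
        """
        if self._label_index is None:
            index: dict[str, set[Curie]] = {}
            for ent in self.entities.values():
                for name in {ent.label, *ent.synonyms}:
                    index.setdefault(name.lower(), set()).add(ent.curie)
            self._label_index = index
        return frozenset(self._label_index.get(label.lower(), frozenset()))

    # -- closures -----------------------------------------------------
    def _edges(self, curie: Curie, relations: frozenset[str]) -> Iterable[Curie]:
        ent = self.entities.get(curie)
        if ent is not None:
            if "part_of" in relations:
                yield from ent.part_of
            if "subclass_of" in relations:
                yield from ent.subclass_of
        if "supplies_to" in relations:
            yield from self.supplies_to.get(curie, ())

    def ancestors(self, start: Curie, relations: Iterable[str]) -> frozenset[Curie]:
        """Reflexive-transitive closure over the union of the relations.

        ``start`` is always included (zero-length path, matching SPARQL
        ``*`` path semantics).  The walk is visited-set guarded so corrupt,
        cyclic edge sets cannot hang it.
        """
        rels = frozenset(relations)
        unknown = rels.difference(RELATIONS)
        if unknown:
            raise ValueError(f"unknown relations: {sorted(unknown)}; expected {RELATIONS}")
        seen: set[Curie] = {start}
        frontier = [start]
        while frontier:
            nxt: list[Curie] = []
            for node in frontier:
                for parent in self._edges(node, rels):
                    if parent not in seen:
                        seen.add(parent)
                        nxt.append(parent)
            frontier = nxt
        return frozenset(seen)

    def is_nerve_like(self, curie: Curie) -> bool:
        """True iff the subclass closure reaches a nerve / nerve plexus /
        nerve fiber class."""
        if curie not in self.entities:
            raise UnknownCurieError(f"unknown CURIE: {curie}")
        for anc in self.ancestors(curie, {"subclass_of"}):
            ent = self.entities.get(anc)
            if ent is not None and ent.label.lower() in NERVE_LIKE_LABELS:
                return True
        return False

    # -- convenience --------------------------------------------------
    def adjacency_for(self, pop_id: Curie):
        """Adjacency edges for a population: stored edges on simple-dialect
        graphs, otherwise derived from the partial-order tree."""
        from .simple import partial_order_to_adjacency  # local import: cycle

        if pop_id in self.adjacency:
            return self.adjacency[pop_id]
        pop = self.populations.get(pop_id)
        if pop is None or pop.path is None:
            return ()
        return tuple(partial_order_to_adjacency(pop.path, pop_id))

    def predecessors_index(self) -> dict[Curie, frozenset[Curie]]:
        """Inverted forward-connection index (post-population -> pre-populations).

        Forward connections are directed pre -> post and not reciprocal; the
        inverse is exposed only through this index, never asserted as triples.
        """
        inv: dict[Curie, set[Curie]] = {}
        for pop in self.populations.values():
            for target in pop.forward_connections:
                inv.setdefault(target, set()).add(pop.id)
        return {k: frozenset(v) for k, v in inv.items()}


def resolve_label(graph: KnowledgeGraph, label: str) -> frozenset[Curie]:
    return graph.resolve_label(label)


def ancestors(graph: KnowledgeGraph, start: Curie, relations: Iterable[str]) -> frozenset[Curie]:
    return graph.ancestors(start, relations)


def is_nerve_like(graph: KnowledgeGraph, curie: Curie) -> bool:
    return graph.is_nerve_like(curie)
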