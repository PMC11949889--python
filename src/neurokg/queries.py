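"""Competency queries over a connectivity knowledge graph.

Four standing questions drive the engine:

1. Which populations terminate in a given organ (anywhere in its part-of
   closure), from where, and through which nerves?
2. Which origins and destinations travel through a given nerve or any of
   its branches (subclass or part-of closure)?
3. Which anatomical structures might be affected by perturbing a given
   structure (everything co-located on populations touching it)?
4. How is autonomic innervation supplied to an end organ — the pre- and
   post-ganglionic populations chained by forward connections, their
   pathway adjacency, and the synapse locations where a pre-ganglionic
   terminal coincides with a post-ganglionic soma?

All queries run over the domain objects, so they give identical answers on
an axiom-level graph (via shortcut materialization) and on a graph loaded
directly from the flat dialect.  Result ordering is deterministic, ties
broken by CURIE lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import pandas as pd

from .simple import ensure_simple
from .store import KnowledgeGraph
from .vocab import (
    ANS_BY_LABEL,
    AnsDivision,
    AnsPhenotype,
    CircuitRole,
    Curie,
    FunctionalRole,
    LocationRole,
    ROLE_ORDER,
    Sex,
)


class Labeled(NamedTuple):
    """A CURIE with its human-readable label."""

    curie: Curie
    label: str


@dataclass(frozen=True)
class ConnectionRow:
    population: Curie
    origin: Labeled
    destination: Labeled
    via: Optional[Labeled] = None
    target_organ: Optional[Labeled] = None

    def sort_key(self):
        return (
            self.population.render(),
            self.origin.curie.render(),
            self.destination.curie.render(),
            self.via.curie.render() if self.via else "",
        )


@dataclass(frozen=True)
class CircuitEdgeRow:
    population: Curie
    v1: Labeled
    v1_role: str
    v2: Labeled
    v2_role: str
    is_synapse: bool

    def sort_key(self):
        return (self.population.render(), self.v1.curie.render(), self.v2.curie.render())


class LabelLookupError(LookupError):
    """A query label resolved to no entity in the graph."""


def _labeled(graph: KnowledgeGraph, curie: Curie) -> Labeled:
    return Labeled(curie, graph.label_of(curie))


def _resolve_or_fail(graph: KnowledgeGraph, label: str, what: str) -> frozenset[Curie]:
    curies = graph.resolve_label(label)
    if not curies:
        raise LabelLookupError(f"{what} label {label!r} resolves to no entity")
    return curies


def connections_terminating_in(
    graph: KnowledgeGraph, organ_label: str, require_nerve_via: bool = True
) -> list[ConnectionRow]:
    """Populations whose terminals lie in the part-of closure of an organ.

    One row per (population, origin, destination, via) combination.  With
    ``require_nerve_via`` (the default, matching the organ-termination
    question) only vias that are nerves, nerve plexuses or nerve fibers
    qualify and a qualifying via is required; without it the via is
    optional and unfiltered, so the result is a superset.
    """
    organ_curies = _resolve_or_fail(graph, organ_label, "organ")
    rows: set[ConnectionRow] = set()
    for pop in graph.populations.values():
        for dest in pop.destinations:
            matched = graph.ancestors(dest, {"part_of"}) & organ_curies
            if not matched:
                continue
            organ = _labeled(graph, min(matched))
            vias = sorted(pop.axon_course)
            if require_nerve_via:
                vias = [v for v in vias if v in graph.entities and graph.is_nerve_like(v)]
                if not vias:
                    continue
            via_options = vias if vias else [None]
            for origin in pop.origins:
                for via in via_options:
                    rows.add(
                        ConnectionRow(
                            population=pop.id,
                            origin=_labeled(graph, origin),
                            destination=_labeled(graph, dest),
                            via=_labeled(graph, via) if via is not None else None,
                            target_organ=organ,
                        )
                    )
    return sorted(rows, key=ConnectionRow.sort_key)


def connections_via(graph: KnowledgeGraph, nerve_label: str) -> list[ConnectionRow]:
    """Origins and destinations of populations routed through a nerve.

    A population qualifies when any of its axon-course locations reaches
    the named nerve through the union of the subclass and part-of closures,
    so branches of the nerve are included.
    """
    nerve_curies = _resolve_or_fail(graph, nerve_label, "nerve")
    rows: set[ConnectionRow] = set()
    for pop in graph.populations.values():
        for via in pop.axon_course:
            if not (graph.ancestors(via, {"subclass_of", "part_of"}) & nerve_curies):
                continue
            for origin in pop.origins:
                for dest in pop.destinations:
                    rows.add(
                        ConnectionRow(
                            population=pop.id,
                            origin=_labeled(graph, origin),
                            destination=_labeled(graph, dest),
                            via=_labeled(graph, via),
                        )
                    )
    return sorted(rows, key=ConnectionRow.sort_key)


def affected_by_perturbation(graph: KnowledgeGraph, structure_label: str) -> frozenset[Labeled]:
    """Structures co-located with a perturbed structure on any population.

    Uses the connected locations (union of every role's location set) of
    each population touching the structure, excluding the structure itself.
    """
    target_curies = _resolve_or_fail(graph, structure_label, "structure")
    affected: set[Curie] = set()
    for pop in graph.populations.values():
        touched = pop.all_locations & target_curies
        if not touched:
            continue
        affected |= pop.all_locations - target_curies
    return frozenset(_labeled(graph, c) for c in affected)


def _parse_ans_phenotype(text: str) -> AnsPhenotype:
    key = text.strip().lower()
    if not key.endswith("phenotype"):
        key = key + " phenotype"
    try:
        return ANS_BY_LABEL[key]
    except KeyError:
        raise ValueError(
            f"unknown autonomic phenotype label {text!r}; expected one of "
            + ", ".join(sorted(repr(p.label) for p in ANS_BY_LABEL.values()))
        ) from None


def innervation_circuit(
    graph: KnowledgeGraph, organ_label: str, ans_phenotype: str
) -> list[CircuitEdgeRow]:
    """Trace how innervation with a given phenotype reaches an end organ.

    Target populations carry the phenotype and have a final terminal inside
    the organ's part-of ∪ supplies-to closure.  The circuit is closed over
    reflexive-transitive forward-connection predecessors (traversal is
    directed pre→post only; predecessors come from an inverted index).  One
    row per pathway-adjacency hop of every circuit member; a hop's end node
    is a synapse when it is an axon-terminal location of its population and
    a soma location of a directly forward-connected population.
    """
    phenotype = _parse_ans_phenotype(ans_phenotype)
    organ_curies = _resolve_or_fail(graph, organ_label, "organ")
    simple = ensure_simple(graph)

    targets: set[Curie] = set()
    for pop in simple.populations.values():
        if pop.phenotypes.ans != phenotype:
            continue
        for dest in pop.destinations:
            if simple.ancestors(dest, {"part_of", "supplies_to"}) & organ_curies:
                targets.add(pop.id)
                break

    predecessors = simple.predecessors_index()
    members: set[Curie] = set(targets)
    frontier = list(targets)
    while frontier:
        nxt = []
        for pop_id in frontier:
            for pre in predecessors.get(pop_id, ()):
                if pre not in members:
                    members.add(pre)
                    nxt.append(pre)
        frontier = nxt

    rows: list[CircuitEdgeRow] = []
    for pop_id in sorted(members, key=lambda c: c.render()):
        pop = simple.populations[pop_id]
        terminal_locs = pop.locs(LocationRole.AXON_TERMINAL)
        partner_somata: frozenset[Curie] = frozenset()
        for target in pop.forward_connections:
            partner = simple.populations.get(target)
            if partner is not None:
                partner_somata |= partner.origins
        for edge in simple.adjacency_for(pop_id):
            v1_roles = pop.roles_of(edge.from_loc)
            v2_roles = pop.roles_of(edge.to_loc)
            rows.append(
                CircuitEdgeRow(
                    population=pop_id,
                    v1=_labeled(simple, edge.from_loc),
                    v1_role=v1_roles[0].simple_predicate if v1_roles else "",
                    v2=_labeled(simple, edge.to_loc),
                    v2_role=v2_roles[0].simple_predicate if v2_roles else "",
                    is_synapse=edge.to_loc in terminal_locs and edge.to_loc in partner_somata,
                )
            )
    return sorted(rows, key=CircuitEdgeRow.sort_key)


# ------------------------------------------------------------ filtering

def filter_populations(
    graph: KnowledgeGraph,
    sex: Optional[str] = None,
    species: Optional[str] = None,
) -> frozenset[Curie]:
    """Population ids matching sex / species filters.

    Sex is closed-world: a sex-specific population is excluded under the
    opposite-sex filter, while populations without sex axioms exist in both
    sexes and match either filter.  Species is open-world: a named-taxon
    filter matches only populations explicitly observed in that taxon
    (label or CURIE), and the ``"unassigned"`` / ``"mammalian"`` filter
    matches exactly the populations with an empty species set.
    """
    selected: set[Curie] = set()
    want_sex = Sex[sex.upper()] if sex is not None else None
    for pop in graph.populations.values():
        if want_sex is not None and pop.sex.sex is not None and pop.sex.sex is not want_sex:
            continue
        if species is not None:
            key = species.strip().lower()
            if key in ("unassigned", "mammalian"):
                if pop.species.taxa:
                    continue
            else:
                names = {t.render().lower() for t in pop.species.taxa} | {
                    graph.label_of(t).lower() for t in pop.species.taxa
                }
                if key not in names:
                    continue
        selected.add(pop.id)
    return frozenset(selected)


# ------------------------------------------------------------- summary

_ROLE_DIMENSION_LABELS = {
    LocationRole.SOMA: "Soma location",
    LocationRole.DENDRITE: "Dendrite location",
    LocationRole.AXON: "Axon location",
    LocationRole.AXON_TO_SENSORY_TERMINAL: "Sensory axon",
    LocationRole.AXON_TERMINAL: "Axon terminal",
    LocationRole.SENSORY_TERMINAL: "Sensory terminal",
}


def phenotype_summary(graph: KnowledgeGraph) -> pd.DataFrame:
    """Population counts per phenotypic dimension.

    Columns: ``dimension``, ``value``, ``population_count``.  Species
    counts are non-exclusive (one population may be observed in several
    taxa); ``Unassigned`` counts populations with an empty species set,
    which are mammalian with the exact species unspecified.  Locational
    rows count populations having at least one location in that role.
    Autonomic counts use the coarse subdivision buckets.
    """
    pops = list(graph.populations.values())
    rows: list[tuple[str, str, int]] = []

    taxa_counts: dict[str, int] = {}
    unassigned = 0
    for pop in pops:
        if not pop.species.taxa:
            unassigned += 1
        for taxon in pop.species.taxa:
            name = graph.label_of(taxon)
            taxa_counts[name] = taxa_counts.get(name, 0) + 1
    for name in sorted(taxa_counts):
        rows.append(("Species", name, taxa_counts[name]))
    rows.append(("Species", "Unassigned", unassigned))

    for sex in (Sex.FEMALE, Sex.MALE):
        rows.append(
            ("Sex", sex.label.capitalize(), sum(1 for p in pops if p.sex.sex is sex))
        )

    for role in ROLE_ORDER:
        rows.append(
            (
                "Locational phenotype",
                _ROLE_DIMENSION_LABELS[role],
                sum(1 for p in pops if p.locs(role)),
            )
        )

    for fr in FunctionalRole:
        rows.append(
            (
                "Functional circuit role",
                fr.value,
                sum(1 for p in pops if p.phenotypes.functional_role is fr),
            )
        )
    for cr in CircuitRole:
        rows.append(
            (
                "Circuit role",
                cr.value,
                sum(1 for p in pops if p.phenotypes.circuit_role is cr),
            )
        )
    for division in AnsDivision:
        rows.append(
            (
                "ANS phenotype",
                division.value,
                sum(
                    1
                    for p in pops
                    if p.phenotypes.ans is not None and p.phenotypes.ans.division is division
                ),
            )
        )
    return pd.DataFrame(rows, columns=["dimension", "value", "population_count"])


# ----------------------------------------------------------- CSV export

def connection_rows_frame(rows: list[ConnectionRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": r.population.render(),
                "origin": r.origin.curie.render(),
                "origin_label": r.origin.label,
                "destination": r.destination.curie.render(),
                "destination_label": r.destination.label,
                "via": r.via.curie.render() if r.via else "",
                "via_label": r.via.label if r.via else "",
                "target_organ": r.target_organ.curie.render() if r.target_organ else "",
                "target_organ_label": r.target_organ.label if r.target_organ else "",
            }
            for r in rows
        ],
        columns=[
            "population",
            "origin",
            "origin_label",
            "destination",
            "destination_label",
            "via",
            "via_label",
            "target_organ",
            "target_organ_label",
        ],
    )


def circuit_rows_frame(rows: list[CircuitEdgeRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": r.population.render(),
                "v1": r.v1.curie.render(),
                "v1_label": r.v1.label,
                "v1_role": r.v1_role,
                "v2": r.v2.curie.render(),
                "v2_label": r.v2.label,
                "v2_role": r.v2_role,
                "is_synapse": "YES" if r.is_synapse else "NO",
            }
            for r in rows
        ],
        columns=["population", "v1", "v1_label", "v1_role", "v2", "v2_label", "v2_role", "is_synapse"],
    )


def affected_frame(result: frozenset[Labeled]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"structure": l.curie.render(), "label": l.label} for l in sorted(result)],
        columns=["structure", "label"],
    )
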