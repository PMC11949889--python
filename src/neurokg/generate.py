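"""Seeded generator of realistic connectivity graphs with a ground-truth ledger.

The generator emulates the structure of a curated autonomic-connectivity
knowledge base: a partonomy of end organs and their parts, a hierarchy of
nerves / nerve plexuses / nerve fibers with partonomic branches, autonomic
ganglia, spinal-cord segments as origins, and neuron populations with
locational phenotypes, autonomic / sex / species annotations and planted
pre→post ganglionic circuits whose members share synapse structures.

Every planted fact is recorded in a :class:`GroundTruthLedger`, and the
test contract is that the query engine recovers the ledger exactly.  The
same ``(config, seed)`` always produces an identical graph, down to the
serialized bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from .model import (
    AnatomicalEntity,
    NeuronPopulation,
    PartialOrderTree,
    PhenotypeAnnotation,
    Provenance,
    SexAssertion,
    SourceKind,
    SpeciesAssertion,
)
from .store import KnowledgeGraph
from .vocab import (
    AnsDivision,
    AnsPhenotype,
    COMMON_TAXA,
    Curie,
    GanglionicOrder,
    LocationRole,
    PrefixRegistry,
    Sex,
)

_GEN_POP_BASE = "http://uri.neurokg.org/populations/gen/"


class ConfigError(ValueError):
    """An infeasible or invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and annotation rates of a generated graph.

    Fractions are per-population probabilities in [0, 1]; the defaults
    mirror the phenotype mix of a curated autonomic knowledge base, where
    sympathetic and parasympathetic populations dominate, roughly a quarter
    of populations are sex-specific (females over-represented through the
    reproductive-system models), and about two thirds carry an explicit
    species observation.
    """

    n_entities: int = 80
    n_populations: int = 20
    partonomy_depth: int = 3
    sympathetic_fraction: float = 0.45
    parasympathetic_fraction: float = 0.3
    enteric_fraction: float = 0.05
    female_fraction: float = 0.18
    male_fraction: float = 0.08
    species_fraction: float = 0.65
    n_circuits: int = 3
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "sympathetic_fraction": self.sympathetic_fraction,
            "parasympathetic_fraction": self.parasympathetic_fraction,
            "enteric_fraction": self.enteric_fraction,
            "female_fraction": self.female_fraction,
            "male_fraction": self.male_fraction,
            "species_fraction": self.species_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.sympathetic_fraction + self.parasympathetic_fraction + self.enteric_fraction > 1:
            raise ConfigError("autonomic-subdivision fractions sum to more than 1")
        if self.female_fraction + self.male_fraction > 1:
            raise ConfigError("sex-specific fractions sum to more than 1")
        for name in ("n_entities", "n_populations", "partonomy_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_circuits < 0:
            raise ConfigError("n_circuits must be non-negative")
        if 2 * self.n_circuits > self.n_populations:
            raise ConfigError(
                f"{self.n_circuits} circuits need {2 * self.n_circuits} populations, "
                f"only {self.n_populations} requested"
            )


@dataclass(frozen=True)
class CircuitRecord:
    """One planted pre→post ganglionic circuit."""

    pre: Curie
    posts: tuple[Curie, ...]
    synapse_locations: frozenset[Curie]
    organ_label: str
    phenotype_label: str


@dataclass
class GroundTruthLedger:
    """Everything the generator planted, keyed the way queries recover it."""

    organ_targets: dict[str, frozenset[Curie]] = field(default_factory=dict)
    nerve_routes: dict[str, frozenset[Curie]] = field(default_factory=dict)
    circuits: list[CircuitRecord] = field(default_factory=list)
    population_locations: dict[Curie, dict[LocationRole, frozenset[Curie]]] = field(
        default_factory=dict
    )
    sex_assignments: dict[Curie, Optional[Sex]] = field(default_factory=dict)
    species_assignments: dict[Curie, frozenset[Curie]] = field(default_factory=dict)


def generate_graph(config: GeneratorConfig) -> tuple[KnowledgeGraph, GroundTruthLedger]:
    """Build a deterministic graph + ledger for the given configuration."""
    config.validate()
    rng = random.Random(config.seed)

    registry = PrefixRegistry({"gen": _GEN_POP_BASE})
    kg = KnowledgeGraph(prefixes=registry)
    ledger = GroundTruthLedger()

    counter = [0]

    def mint(label: str) -> Curie:
        counter[0] += 1
        c = Curie("ILX", f"09{counter[0]:05d}")
        kg.add_entity(AnatomicalEntity(c, label))
        return c

    nerve_root = Curie.parse("UBERON:0001021")
    ganglion_root = Curie.parse("UBERON:0000045")
    kg.add_entity(AnatomicalEntity(nerve_root, "nerve"))
    kg.add_entity(AnatomicalEntity(ganglion_root, "ganglion"))
    plexus_root = mint("nerve plexus")
    fiber_root = mint("nerve fiber")
    kg.add_entity(
        replace(kg.entities[plexus_root], subclass_of=frozenset({nerve_root}))
    )
    kg.add_entity(replace(kg.entities[fiber_root], subclass_of=frozenset({nerve_root})))
    conduit_roots = [nerve_root, plexus_root, fiber_root]

    # spinal segments as the origin pool
    segments = [mint(f"generated spinal segment {i + 1}") for i in range(8)]

    # organ partonomy: each organ owns a chain of parts of configured depth
    n_organs = max(config.n_circuits + 1, config.n_entities // 12)
    organ_parts: dict[str, list[Curie]] = {}
    organ_roots: dict[str, Curie] = {}
    for o in range(n_organs):
        label = f"generated organ {o + 1}"
        root = mint(label)
        organ_roots[label] = root
        parts = [root]
        parent = root
        for d in range(config.partonomy_depth):
            part = mint(f"{label} region {d + 1}")
            kg.add_entity(replace(kg.entities[part], part_of=frozenset({parent})))
            parts.append(part)
            parent = part
        organ_parts[label] = parts

    # nerve hierarchy: top nerves with partonomic branches
    n_nerves = max(2, n_organs)
    nerve_tops: dict[str, Curie] = {}
    nerve_members: dict[str, list[Curie]] = {}
    for n in range(n_nerves):
        label = f"generated nerve {n + 1}"
        kind = conduit_roots[n % len(conduit_roots)]
        top = mint(label)
        kg.add_entity(replace(kg.entities[top], subclass_of=frozenset({kind})))
        members = [top]
        for b in range(1 + n % 2):
            branch = mint(f"branch {b + 1} of {label}")
            kg.add_entity(
                replace(
                    kg.entities[branch],
                    part_of=frozenset({top}),
                    subclass_of=frozenset({kind}),
                )
            )
            members.append(branch)
        nerve_tops[label] = top
        nerve_members[label] = members

    ganglia = [mint(f"generated autonomic ganglion {k + 1}") for k in range(config.n_circuits + 2)]
    for gang in ganglia:
        kg.add_entity(replace(kg.entities[gang], subclass_of=frozenset({ganglion_root})))

    taxa = sorted(COMMON_TAXA)
    organ_labels = sorted(organ_parts)
    circuit_organs = organ_labels[: config.n_circuits]
    background_organs = organ_labels[config.n_circuits:]
    nerve_labels = sorted(nerve_members)

    organ_targets: dict[str, set[Curie]] = {label: set() for label in organ_labels}
    nerve_routes: dict[str, set[Curie]] = {label: set() for label in nerve_labels}

    def draw_sex(rng: random.Random) -> Optional[Sex]:
        u = rng.random()
        if u < config.female_fraction:
            return Sex.FEMALE
        if u < config.female_fraction + config.male_fraction:
            return Sex.MALE
        return None

    def draw_species(rng: random.Random) -> frozenset[Curie]:
        if rng.random() < config.species_fraction:
            return frozenset({Curie.parse(rng.choice(taxa))})
        return frozenset()

    def draw_ans(rng: random.Random) -> Optional[AnsPhenotype]:
        u = rng.random()
        if u < config.sympathetic_fraction:
            return AnsPhenotype(AnsDivision.SYMPATHETIC)
        u -= config.sympathetic_fraction
        if u < config.parasympathetic_fraction:
            return AnsPhenotype(AnsDivision.PARASYMPATHETIC)
        u -= config.parasympathetic_fraction
        if u < config.enteric_fraction:
            return AnsPhenotype(AnsDivision.ENTERIC)
        return None

    def register_population(pop: NeuronPopulation) -> None:
        kg.add_population(pop)
        ledger.population_locations[pop.id] = dict(pop.locations)
        ledger.sex_assignments[pop.id] = pop.sex.sex
        ledger.species_assignments[pop.id] = pop.species.taxa

    def make_population(
        index: int,
        soma: Curie,
        via: Curie,
        terminal: Curie,
        ans: Optional[AnsPhenotype],
        forward: frozenset[Curie] = frozenset(),
    ) -> NeuronPopulation:
        pop_id = Curie("gen", str(index))
        return NeuronPopulation(
            id=pop_id,
            label=f"generated neuron population {index}",
            locations={
                LocationRole.SOMA: frozenset({soma}),
                LocationRole.AXON: frozenset({via}),
                LocationRole.AXON_TERMINAL: frozenset({terminal}),
            },
            path=PartialOrderTree.chain([soma, via, terminal]),
            phenotypes=PhenotypeAnnotation(ans=ans),
            species=SpeciesAssertion(draw_species(rng)),
            sex=SexAssertion(draw_sex(rng)),
            forward_connections=forward,
            provenance=Provenance(
                source_kind=SourceKind.LITERATURE if index % 3 else SourceKind.EXPERT_MODEL
            ),
        )

    index = 0
    # planted circuits on their reserved organs
    for k in range(config.n_circuits):
        organ_label = circuit_organs[k]
        ganglion = ganglia[k]
        nerve_label_pre = nerve_labels[(2 * k) % len(nerve_labels)]
        nerve_label_post = nerve_labels[(2 * k + 1) % len(nerve_labels)]
        via_pre = rng.choice(nerve_members[nerve_label_pre])
        via_post = rng.choice(nerve_members[nerve_label_post])
        terminal = rng.choice(organ_parts[organ_label][1:])
        soma = rng.choice(segments)

        index += 1
        post = make_population(
            index + 1,  # id assigned below; placeholder to keep rng order stable
            ganglion,
            via_post,
            terminal,
            AnsPhenotype(AnsDivision.SYMPATHETIC, GanglionicOrder.POST_GANGLIONIC),
        )
        pre = make_population(
            index,
            soma,
            via_pre,
            ganglion,
            AnsPhenotype(AnsDivision.SYMPATHETIC, GanglionicOrder.PRE_GANGLIONIC),
            forward=frozenset({post.id}),
        )
        index += 1
        register_population(pre)
        register_population(post)
        organ_targets[organ_label].add(post.id)
        nerve_routes[nerve_label_pre].add(pre.id)
        nerve_routes[nerve_label_post].add(post.id)
        ledger.circuits.append(
            CircuitRecord(
                pre=pre.id,
                posts=(post.id,),
                synapse_locations=frozenset({ganglion}),
                organ_label=organ_label,
                phenotype_label=AnsPhenotype(
                    AnsDivision.SYMPATHETIC, GanglionicOrder.POST_GANGLIONIC
                ).label,
            )
        )

    # background populations on the remaining organs
    while index < config.n_populations:
        index += 1
        organ_label = rng.choice(background_organs)
        nerve_label = rng.choice(nerve_labels)
        soma = rng.choice(segments)
        via = rng.choice(nerve_members[nerve_label])
        terminal = rng.choice(organ_parts[organ_label])
        ans = draw_ans(rng)
        # keep reserved circuit organs free of extra post-ganglionic content
        if ans is not None and ans.division is AnsDivision.SYMPATHETIC:
            ans = AnsPhenotype(AnsDivision.SYMPATHETIC, GanglionicOrder.UNSPECIFIED)
        pop = make_population(index, soma, via, terminal, ans)
        register_population(pop)
        organ_targets[organ_label].add(pop.id)
        nerve_routes[nerve_label].add(pop.id)

    ledger.organ_targets = {k: frozenset(v) for k, v in organ_targets.items()}
    ledger.nerve_routes = {k: frozenset(v) for k, v in nerve_routes.items()}
    return kg, ledger
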