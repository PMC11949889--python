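"""Bundled worked-example connectivity graphs.

Five small graphs exercise every layer without any download:

* ``prostate`` — the sympathetic pre-ganglionic population "L2-L5 spinal
  cord to inferior mesenteric ganglion via lumbar splanchnic nerve",
  including its branching partial-order tree and the forward-connection
  stub it points at.  Anatomical identifiers are the real UBERON terms.
* ``femrep`` — the sympathetic innervation circuit of the ovary in female
  rats: one pre-ganglionic population from the T9-T10 spinal segments to
  three paravertebral-chain locations via the white communicating rami,
  synapsing onto two post-ganglionic populations that travel through the
  ovarian nerve plexus, one terminating in the left and one in the right
  ovary.
* ``salivary`` — a parasympathetic pre-ganglionic pathway from the
  superior salivatory nucleus to the pterygopalatine ganglion whose axon
  travels the facial nerve, then the greater petrosal nerve, then the
  vidian nerve, in that order.
* ``bladder_toy`` — ten populations of which exactly six terminate
  somewhere in the urinary bladder partonomy, for organ-termination
  queries.
* ``vagus_toy`` — a small vagus-nerve branch hierarchy (with the nodose
  ganglion synonym) and populations routed via the trunk, via branches,
  and via an unrelated nerve, for nerve-routing queries.

CURIEs not printed in any public listing are synthetic: they are minted in
the ILX namespace for this package's fixtures and are non-authoritative.
"""

from __future__ import annotations

from .model import (
    AnatomicalEntity,
    Citation,
    CitationKind,
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
    CircuitRole,
    Curie,
    GanglionicOrder,
    LocationRole,
    PrefixRegistry,
    Sex,
)

FIXTURE_NAMES = ("prostate", "femrep", "bladder_toy", "vagus_toy", "salivary")

_POP_BASE = "http://uri.neurokg.org/populations/"

# widely used anatomical terms shared across fixtures
NERVE = Curie.parse("UBERON:0001021")
GANGLION = Curie.parse("UBERON:0000045")
NERVE_PLEXUS = Curie.parse("ILX:0100001")  # synthetic id, canonical label
NERVE_FIBER = Curie.parse("ILX:0100002")  # synthetic id, canonical label

RAT = Curie.parse("NCBITaxon:10116")
DOG = Curie.parse("NCBITaxon:9615")


def _c(text: str) -> Curie:
    return Curie.parse(text)


def _base_graph(pop_prefix: str) -> KnowledgeGraph:
    registry = PrefixRegistry({pop_prefix: _POP_BASE + pop_prefix + "/"})
    kg = KnowledgeGraph(prefixes=registry)
    kg.add_entity(AnatomicalEntity(NERVE, "nerve"))
    kg.add_entity(AnatomicalEntity(GANGLION, "ganglion"))
    kg.add_entity(AnatomicalEntity(NERVE_PLEXUS, "nerve plexus", subclass_of={NERVE}))
    kg.add_entity(AnatomicalEntity(NERVE_FIBER, "nerve fiber", subclass_of={NERVE}))
    return kg


def _pot(node: Curie, *children: PartialOrderTree) -> PartialOrderTree:
    return PartialOrderTree(node, children)


# ----------------------------------------------------------------- prostate

L2 = _c("UBERON:0006450")
L3 = _c("UBERON:0006449")
L4 = _c("UBERON:0006451")
L5 = _c("UBERON:0006447")
LUMBAR_SPLANCHNIC = _c("UBERON:0018683")
IMG = _c("UBERON:0005453")


def build_prostate() -> KnowledgeGraph:
    kg = _base_graph("prostate")
    kg.add_entity(AnatomicalEntity(L2, "L2 segment of lumbar spinal cord"))
    kg.add_entity(AnatomicalEntity(L3, "L3 segment of lumbar spinal cord"))
    kg.add_entity(AnatomicalEntity(L4, "L4 segment of lumbar spinal cord"))
    kg.add_entity(AnatomicalEntity(L5, "L5 segment of lumbar spinal cord"))
    kg.add_entity(
        AnatomicalEntity(LUMBAR_SPLANCHNIC, "lumbar splanchnic nerve", subclass_of={NERVE})
    )
    kg.add_entity(
        AnatomicalEntity(IMG, "inferior mesenteric ganglion", subclass_of={GANGLION})
    )

    path = PartialOrderTree.root(
        [
            _pot(L5, _pot(LUMBAR_SPLANCHNIC, _pot(IMG))),
            _pot(L2, _pot(LUMBAR_SPLANCHNIC)),
            _pot(L3, _pot(LUMBAR_SPLANCHNIC)),
            _pot(L4, _pot(LUMBAR_SPLANCHNIC)),
        ]
    )
    kg.add_population(
        NeuronPopulation(
            id=_c("prostate:24"),
            label="neuron type prostate 24",
            pref_label=(
                "L2-L5 spinal cord to inferior mesenteric ganglion via lumbar splanchic nerve"
            ),
            locations={
                LocationRole.SOMA: frozenset({L2, L3, L4, L5}),
                LocationRole.AXON: frozenset({LUMBAR_SPLANCHNIC}),
                LocationRole.AXON_TERMINAL: frozenset({IMG}),
            },
            path=path,
            phenotypes=PhenotypeAnnotation(
                ans=AnsPhenotype(AnsDivision.SYMPATHETIC, GanglionicOrder.PRE_GANGLIONIC)
            ),
            species=SpeciesAssertion(frozenset({DOG})),
            sex=SexAssertion(Sex.MALE),
            forward_connections=frozenset({_c("prostate:25")}),
            provenance=Provenance(
                citations=frozenset({Citation(CitationKind.PMID, "squib-prostate-24")}),
                source_kind=SourceKind.LITERATURE,
            ),
        )
    )
    kg.add_stub(_c("prostate:25"), "neuron type prostate 25")
    return kg


# ------------------------------------------------------------------- femrep

T9 = _c("ILX:0791001")
T10 = _c("ILX:0791002")
WHITE_RAMI = _c("ILX:0791003")
CHAIN_T12 = _c("ILX:0791004")
CHAIN_T13 = _c("ILX:0791005")
CHAIN_L1 = _c("ILX:0791006")
OVARIAN_PLEXUS = _c("ILX:0791007")
OVARY = _c("UBERON:0000992")
LEFT_OVARY = _c("ILX:0791008")
RIGHT_OVARY = _c("ILX:0791009")
CHAIN_LOCATIONS = frozenset({CHAIN_T12, CHAIN_T13, CHAIN_L1})


def build_femrep() -> KnowledgeGraph:
    kg = _base_graph("femrep")
    kg.add_entity(AnatomicalEntity(T9, "T9 segment of thoracic spinal cord"))
    kg.add_entity(AnatomicalEntity(T10, "T10 segment of thoracic spinal cord"))
    kg.add_entity(
        AnatomicalEntity(WHITE_RAMI, "white communicating rami of T9-T10", subclass_of={NERVE})
    )
    kg.add_entity(
        AnatomicalEntity(
            CHAIN_T12, "T12 paravertebral sympathetic chain ganglion", subclass_of={GANGLION}
        )
    )
    kg.add_entity(
        AnatomicalEntity(
            CHAIN_T13, "T13 paravertebral sympathetic chain ganglion", subclass_of={GANGLION}
        )
    )
    kg.add_entity(
        AnatomicalEntity(
            CHAIN_L1, "L1 paravertebral sympathetic chain ganglion", subclass_of={GANGLION}
        )
    )
    kg.add_entity(
        AnatomicalEntity(OVARIAN_PLEXUS, "ovarian nerve plexus", subclass_of={NERVE_PLEXUS})
    )
    kg.add_entity(AnatomicalEntity(OVARY, "ovary"))
    kg.add_entity(AnatomicalEntity(LEFT_OVARY, "left ovary", part_of={OVARY}))
    kg.add_entity(AnatomicalEntity(RIGHT_OVARY, "right ovary", part_of={OVARY}))

    female_rat = dict(
        species=SpeciesAssertion(frozenset({RAT})),
        sex=SexAssertion(Sex.FEMALE),
        provenance=Provenance(
            citations=frozenset({Citation(CitationKind.DOI, "10.0000/synthetic-femrep")}),
            source_kind=SourceKind.LITERATURE,
        ),
    )

    pre_path = PartialOrderTree.root(
        [
            _pot(
                soma,
                _pot(WHITE_RAMI, _pot(CHAIN_T12), _pot(CHAIN_T13), _pot(CHAIN_L1)),
            )
            for soma in (T9, T10)
        ]
    )
    kg.add_population(
        NeuronPopulation(
            id=_c("femrep:36"),
            label="neuron type femrep 36",
            pref_label=(
                "T9-T10 spinal cord to T12-L1 paravertebral sympathetic chain "
                "via white communicating rami of T9-10"
            ),
            locations={
                LocationRole.SOMA: frozenset({T9, T10}),
                LocationRole.AXON: frozenset({WHITE_RAMI}),
                LocationRole.AXON_TERMINAL: CHAIN_LOCATIONS,
            },
            path=pre_path,
            phenotypes=PhenotypeAnnotation(
                ans=AnsPhenotype(AnsDivision.SYMPATHETIC, GanglionicOrder.PRE_GANGLIONIC)
            ),
            forward_connections=frozenset({_c("femrep:37"), _c("femrep:40-1")}),
            **female_rat,
        )
    )
    for pop_num, target, side in (("37", LEFT_OVARY, "left"), ("40-1", RIGHT_OVARY, "right")):
        post_path = PartialOrderTree.root(
            [
                _pot(chain, _pot(OVARIAN_PLEXUS, _pot(target)))
                for chain in sorted(CHAIN_LOCATIONS)
            ]
        )
        kg.add_population(
            NeuronPopulation(
                id=_c(f"femrep:{pop_num}"),
                label=f"neuron type femrep {pop_num}",
                pref_label=(
                    f"T12-L1 paravertebral sympathetic chain to {side} ovary "
                    "via ovarian nerve plexus"
                ),
                locations={
                    LocationRole.SOMA: CHAIN_LOCATIONS,
                    LocationRole.AXON: frozenset({OVARIAN_PLEXUS}),
                    LocationRole.AXON_TERMINAL: frozenset({target}),
                },
                path=post_path,
                phenotypes=PhenotypeAnnotation(
                    ans=AnsPhenotype(AnsDivision.SYMPATHETIC, GanglionicOrder.POST_GANGLIONIC)
                ),
                **female_rat,
            )
        )
    return kg


# ----------------------------------------------------------------- salivary

SSN = _c("ILX:0792001")
FACIAL_NERVE = _c("UBERON:0001647")
GREATER_PETROSAL = _c("ILX:0792002")
VIDIAN_NERVE = _c("ILX:0792003")
PTERYGOPALATINE = _c("ILX:0792004")


def build_salivary() -> KnowledgeGraph:
    kg = _base_graph("salivary")
    kg.add_entity(AnatomicalEntity(SSN, "superior salivatory nucleus"))
    kg.add_entity(AnatomicalEntity(FACIAL_NERVE, "facial nerve", subclass_of={NERVE}))
    kg.add_entity(
        AnatomicalEntity(GREATER_PETROSAL, "greater petrosal nerve", subclass_of={NERVE})
    )
    kg.add_entity(
        AnatomicalEntity(
            VIDIAN_NERVE,
            "vidian nerve",
            synonyms={"nerve of pterygoid canal"},
            subclass_of={NERVE},
        )
    )
    kg.add_entity(
        AnatomicalEntity(PTERYGOPALATINE, "pterygopalatine ganglion", subclass_of={GANGLION})
    )
    kg.add_population(
        NeuronPopulation(
            id=_c("salivary:1"),
            label="neuron type salivary 1",
            pref_label=(
                "superior salivatory nucleus to pterygopalatine ganglion via facial nerve, "
                "greater petrosal nerve and vidian nerve"
            ),
            locations={
                LocationRole.SOMA: frozenset({SSN}),
                LocationRole.AXON: frozenset({FACIAL_NERVE, GREATER_PETROSAL, VIDIAN_NERVE}),
                LocationRole.AXON_TERMINAL: frozenset({PTERYGOPALATINE}),
            },
            path=PartialOrderTree.chain(
                [SSN, FACIAL_NERVE, GREATER_PETROSAL, VIDIAN_NERVE, PTERYGOPALATINE]
            ),
            phenotypes=PhenotypeAnnotation(
                ans=AnsPhenotype(AnsDivision.PARASYMPATHETIC, GanglionicOrder.PRE_GANGLIONIC)
            ),
            provenance=Provenance(source_kind=SourceKind.EXPERT_MODEL),
        )
    )
    return kg


# -------------------------------------------------------------- bladder toy

BLADDER = _c("UBERON:0001255")
BLADDER_NECK = _c("UBERON:0001258")
BLADDER_DOME = _c("ILX:0793001")
BLADDER_NERVE = _c("ILX:0793002")
PELVIC_SPLANCHNIC = _c("ILX:0793003")
HYPOGASTRIC = _c("ILX:0793004")
COLON = _c("ILX:0793005")
COLON_WALL = _c("ILX:0793006")
COLONIC_NERVE = _c("ILX:0793007")

#: Populations planted to terminate within the bladder partonomy.
BLADDER_PLANTED = frozenset(_c(f"bladder:{i}") for i in range(1, 7))


def build_bladder_toy() -> KnowledgeGraph:
    kg = _base_graph("bladder")
    kg.add_entity(AnatomicalEntity(BLADDER, "urinary bladder"))
    kg.add_entity(
        AnatomicalEntity(BLADDER_NECK, "neck of urinary bladder", part_of={BLADDER})
    )
    kg.add_entity(AnatomicalEntity(BLADDER_DOME, "dome of urinary bladder", part_of={BLADDER}))
    kg.add_entity(AnatomicalEntity(BLADDER_NERVE, "bladder nerve", subclass_of={NERVE}))
    kg.add_entity(
        AnatomicalEntity(PELVIC_SPLANCHNIC, "pelvic splanchnic nerve", subclass_of={NERVE})
    )
    kg.add_entity(AnatomicalEntity(HYPOGASTRIC, "hypogastric nerve", subclass_of={NERVE}))
    kg.add_entity(AnatomicalEntity(COLON, "descending colon"))
    kg.add_entity(AnatomicalEntity(COLON_WALL, "wall of descending colon", part_of={COLON}))
    kg.add_entity(AnatomicalEntity(COLONIC_NERVE, "lumbar colonic nerve", subclass_of={NERVE}))

    somata = {}
    for i in range(1, 11):
        soma = _c(f"ILX:07931{i:02d}")
        kg.add_entity(AnatomicalEntity(soma, f"toy spinal segment {i}"))
        somata[i] = soma

    plan = {
        1: (BLADDER_NECK, BLADDER_NERVE),
        2: (BLADDER_NECK, PELVIC_SPLANCHNIC),
        3: (BLADDER_DOME, HYPOGASTRIC),
        4: (BLADDER_DOME, PELVIC_SPLANCHNIC),
        5: (BLADDER, BLADDER_NERVE),
        6: (BLADDER, HYPOGASTRIC),
        7: (COLON_WALL, COLONIC_NERVE),
        8: (COLON_WALL, COLONIC_NERVE),
        9: (COLON, COLONIC_NERVE),
        10: (COLON, COLONIC_NERVE),
    }
    for i, (terminal, via) in plan.items():
        sex = SexAssertion(Sex.FEMALE if i == 1 else Sex.MALE if i == 2 else None)
        species = SpeciesAssertion(frozenset({RAT}) if i <= 3 else frozenset())
        kg.add_population(
            NeuronPopulation(
                id=_c(f"bladder:{i}"),
                label=f"neuron type bladder toy {i}",
                locations={
                    LocationRole.SOMA: frozenset({somata[i]}),
                    LocationRole.AXON: frozenset({via}),
                    LocationRole.AXON_TERMINAL: frozenset({terminal}),
                },
                path=PartialOrderTree.chain([somata[i], via, terminal]),
                phenotypes=PhenotypeAnnotation(
                    ans=AnsPhenotype(AnsDivision.PARASYMPATHETIC)
                    if i % 2
                    else AnsPhenotype(AnsDivision.SYMPATHETIC)
                ),
                sex=sex,
                species=species,
            )
        )
    return kg


# ---------------------------------------------------------------- vagus toy

VAGUS = _c("UBERON:0001759")
SLN = _c("ILX:0794001")
SLN_INTERNAL = _c("ILX:0794002")
NODOSE = _c("ILX:0794003")
ESOPHAGUS_TOY = _c("ILX:0794004")
STOMACH_TOY = _c("ILX:0794005")
DMV = _c("ILX:0794006")
PELVIC_SPLANCHNIC_VT = _c("ILX:0794007")
PELVIC_GANGLION_VT = _c("ILX:0794008")
SACRAL_SEGMENT = _c("ILX:0794009")


def build_vagus_toy() -> KnowledgeGraph:
    kg = _base_graph("vagustoy")
    kg.add_entity(AnatomicalEntity(VAGUS, "vagus nerve", subclass_of={NERVE}))
    kg.add_entity(
        AnatomicalEntity(
            SLN, "superior laryngeal nerve", part_of={VAGUS}, subclass_of={NERVE}
        )
    )
    kg.add_entity(
        AnatomicalEntity(
            SLN_INTERNAL,
            "internal branch of superior laryngeal nerve",
            part_of={SLN},
            subclass_of={NERVE},
        )
    )
    kg.add_entity(
        AnatomicalEntity(
            NODOSE,
            "inferior vagus X ganglion",
            synonyms={"nodose ganglion"},
            subclass_of={GANGLION},
        )
    )
    kg.add_entity(AnatomicalEntity(ESOPHAGUS_TOY, "toy esophagus"))
    kg.add_entity(AnatomicalEntity(STOMACH_TOY, "toy stomach"))
    kg.add_entity(AnatomicalEntity(DMV, "dorsal motor nucleus of vagus nerve"))
    kg.add_entity(
        AnatomicalEntity(PELVIC_SPLANCHNIC_VT, "pelvic splanchnic nerve", subclass_of={NERVE})
    )
    kg.add_entity(
        AnatomicalEntity(PELVIC_GANGLION_VT, "pelvic ganglion", subclass_of={GANGLION})
    )
    kg.add_entity(AnatomicalEntity(SACRAL_SEGMENT, "toy sacral segment"))

    def add(i, soma, terminal, via, *, sensory=False):
        if sensory:
            locations = {
                LocationRole.SOMA: frozenset({soma}),
                LocationRole.AXON_TO_SENSORY_TERMINAL: frozenset({via}),
                LocationRole.SENSORY_TERMINAL: frozenset({terminal}),
            }
        else:
            locations = {
                LocationRole.SOMA: frozenset({soma}),
                LocationRole.AXON: frozenset({via}),
                LocationRole.AXON_TERMINAL: frozenset({terminal}),
            }
        kg.add_population(
            NeuronPopulation(
                id=_c(f"vagustoy:{i}"),
                label=f"neuron type vagus toy {i}",
                locations=locations,
                path=PartialOrderTree.chain([soma, via, terminal]),
                phenotypes=PhenotypeAnnotation(
                    circuit_role=CircuitRole.SENSORY if sensory else None,
                    ans=None
                    if sensory
                    else AnsPhenotype(AnsDivision.PARASYMPATHETIC, GanglionicOrder.PRE_GANGLIONIC),
                ),
            )
        )

    add(1, DMV, STOMACH_TOY, VAGUS)
    add(2, NODOSE, ESOPHAGUS_TOY, SLN_INTERNAL, sensory=True)
    add(3, DMV, ESOPHAGUS_TOY, SLN)
    add(4, SACRAL_SEGMENT, PELVIC_GANGLION_VT, PELVIC_SPLANCHNIC_VT)
    return kg


_BUILDERS = {
    "prostate": build_prostate,
    "femrep": build_femrep,
    "bladder_toy": build_bladder_toy,
    "vagus_toy": build_vagus_toy,
    "salivary": build_salivary,
}


def load_fixture(name: str) -> KnowledgeGraph:
    """Build a named fixture graph (axiom-level dialect)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; expected one of {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


def dump_fixture(name: str, dialect: str = "owl") -> str:
    """Serialize a fixture as Turtle in either dialect."""
    from .owl_io import graph_to_owl
    from .simple import write_simple_ttl

    kg = load_fixture(name)
    if dialect == "owl":
        return graph_to_owl(kg)
    if dialect == "simple":
        return write_simple_ttl(kg)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'owl' or 'simple'")
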