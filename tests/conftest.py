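import random

import pytest

from neurokg import (
    AnatomicalEntity,
    AnsDivision,
    AnsPhenotype,
    Citation,
    CitationKind,
    Curie,
    GanglionicOrder,
    KnowledgeGraph,
    LocationRole,
    NeuronPopulation,
    PartialOrderTree,
    PhenotypeAnnotation,
    PrefixRegistry,
    Provenance,
    Sex,
    SexAssertion,
    SourceKind,
    SpeciesAssertion,
    load_fixture,
)


@pytest.fixture(scope="session")
def prostate_graph():
    return load_fixture("prostate")


@pytest.fixture(scope="session")
def femrep_graph():
    return load_fixture("femrep")


@pytest.fixture(scope="session")
def bladder_graph():
    return load_fixture("bladder_toy")


@pytest.fixture(scope="session")
def vagus_graph():
    return load_fixture("vagus_toy")


@pytest.fixture(scope="session")
def salivary_graph():
    return load_fixture("salivary")


TAXA = ["NCBITaxon:10116", "NCBITaxon:9606", "NCBITaxon:10090", "NCBITaxon:9615"]


def random_population(rng: random.Random, index: int, n_entities: int = 30) -> NeuronPopulation:
    """A structurally valid population with randomized optional fields.

    Exercises every serializable feature: multiple somata, optional
    dendrites and sensory roles, species sets of size 0-2, both sexes,
    all phenotype dimensions, forward connections, citations and notes.
    """
    ent = lambda i: Curie("ILX", f"1{i:06d}")  # noqa: E731
    pool = [ent(i) for i in range(n_entities)]
    somata = frozenset(rng.sample(pool, rng.randint(1, 3)))
    vias = frozenset(rng.sample(pool, rng.randint(0, 2)))
    terminals = frozenset(rng.sample(pool, rng.randint(1, 2)))
    locations = {LocationRole.SOMA: somata, LocationRole.AXON_TERMINAL: terminals}
    if vias:
        locations[LocationRole.AXON] = vias
    if rng.random() < 0.3:
        locations[LocationRole.DENDRITE] = frozenset(rng.sample(pool, 1))
    if rng.random() < 0.3:
        locations[LocationRole.SENSORY_TERMINAL] = frozenset(rng.sample(pool, 1))
        locations[LocationRole.AXON_TO_SENSORY_TERMINAL] = frozenset(rng.sample(pool, 1))

    path = None
    if vias and rng.random() < 0.8:
        via = sorted(vias)[0]
        terminal = sorted(terminals)[0]
        path = PartialOrderTree.root(
            [
                PartialOrderTree(
                    soma,
                    (PartialOrderTree(via, (PartialOrderTree(terminal),)),),
                )
                for soma in sorted(somata)
            ]
        )

    ans = None
    if rng.random() < 0.7:
        ans = AnsPhenotype(
            rng.choice(list(AnsDivision)), rng.choice(list(GanglionicOrder))
        )
    sex = rng.choice([None, Sex.MALE, Sex.FEMALE])
    taxa = frozenset(Curie.parse(t) for t in rng.sample(TAXA, rng.randint(0, 2)))
    forward = frozenset(
        {Curie("pop", str(rng.randrange(1000)))} if rng.random() < 0.4 else set()
    )
    citations = frozenset(
        {Citation(rng.choice(list(CitationKind)), f"ref-{rng.randrange(100)}")}
        if rng.random() < 0.6
        else set()
    )
    notes = ("laterality differs between sides",) if rng.random() < 0.2 else ()
    return NeuronPopulation(
        id=Curie("pop", str(index)),
        label=f"random population {index}",
        pref_label=f"random population {index} preferred",
        locations=locations,
        path=path,
        phenotypes=PhenotypeAnnotation(ans=ans),
        species=SpeciesAssertion(taxa),
        sex=SexAssertion(sex),
        forward_connections=forward,
        provenance=Provenance(
            citations=citations,
            alert_notes=notes,
            source_kind=rng.choice(list(SourceKind)),
        ),
    )


def random_population_graph(seed: int, n_pops: int = 5) -> KnowledgeGraph:
    rng = random.Random(seed)
    registry = PrefixRegistry({"pop": "http://uri.neurokg.org/populations/pop/"})
    kg = KnowledgeGraph(prefixes=registry)
    pops = [random_population(rng, i) for i in range(n_pops)]
    for pop in pops:
        for loc in sorted(pop.all_locations):
            if loc not in kg.entities:
                kg.add_entity(AnatomicalEntity(loc, f"structure {loc.local_id}"))
        kg.add_population(pop)
        for target in pop.forward_connections:
            if target not in kg.populations:
                kg.add_stub(target, f"stub {target.local_id}")
    return kg
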