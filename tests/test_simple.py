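"""Shortcut materialization, adjacency derivation, dialect equivalence."""

import pytest

from neurokg import (
    Curie,
    LocationRole,
    PartialOrderTree,
    graph_to_owl,
    load_fixture,
    partial_order_to_adjacency,
    read_simple_ttl,
    tree_nodes,
    to_simple_graph,
    write_simple_ttl,
)
from neurokg.fixtures import IMG, L2, L3, L4, L5, LUMBAR_SPLANCHNIC
from neurokg.generate import GeneratorConfig, generate_graph
from neurokg.simple import (
    SHORTCUT_MAPPING,
    AdjacencyEdge,
    TransformReport,
    materialize_triples_for,
    origins_destinations_owl_pattern,
    origins_destinations_simple_pattern,
)

P24 = Curie.parse("prostate:24")


class TestShortcutMapping:
    def test_total_and_bijective_on_location_roles(self):
        owl_side = {role.owl_property for role in LocationRole}
        assert owl_side <= set(SHORTCUT_MAPPING)
        simple_side = [SHORTCUT_MAPPING[p] for p in sorted(owl_side)]
        assert len(simple_side) == len(set(simple_side))

    def test_worked_example_shortcut_counts(self, prostate_graph):
        pop = prostate_graph.populations[P24]
        triples = materialize_triples_for(pop)
        by_pred = {}
        for t in triples:
            by_pred.setdefault(t.predicate.local_id, []).append(t.object)
        assert len(by_pred["hasSomaLocation"]) == 4
        assert len(by_pred["hasAxonLocation"]) == 1
        assert len(by_pred["hasAxonTerminalLocation"]) == 1
        assert len(by_pred["hasForwardConnection"]) == 1
        # connected locations = union over all roles: 4 somata + axon + terminal
        assert len(by_pred["hasConnectedLocation"]) == 6

    def test_sex_negation_gets_excluded_sex_triple(self, prostate_graph):
        pop = prostate_graph.populations[P24]  # male-specific
        preds = {t.predicate.local_id for t in materialize_triples_for(pop)}
        assert "hasBiologicalSex" in preds
        assert "hasExcludedBiologicalSex" in preds


class TestAdjacency:
    def test_worked_example_yields_five_distinct_edges(self, prostate_graph):
        pop = prostate_graph.populations[P24]
        edges = partial_order_to_adjacency(pop.path, P24)
        assert len(edges) == 5
        assert set(edges) == {
            AdjacencyEdge(L5, LUMBAR_SPLANCHNIC, P24),
            AdjacencyEdge(L2, LUMBAR_SPLANCHNIC, P24),
            AdjacencyEdge(L3, LUMBAR_SPLANCHNIC, P24),
            AdjacencyEdge(L4, LUMBAR_SPLANCHNIC, P24),
            AdjacencyEdge(LUMBAR_SPLANCHNIC, IMG, P24),
        }

    def test_linear_chain(self):
        a, b, c = (Curie.parse(f"ILX:000000{i}") for i in "123")
        pop = Curie.parse("pop:1")
        edges = partial_order_to_adjacency(PartialOrderTree.chain([a, b, c]), pop)
        assert edges == [AdjacencyEdge(a, b, pop), AdjacencyEdge(b, c, pop)]

    def test_blank_root_with_single_leaf_has_no_edges(self):
        tree = PartialOrderTree.root([PartialOrderTree(Curie.parse("ILX:0000001"))])
        assert partial_order_to_adjacency(tree, Curie.parse("pop:1")) == []

    def test_edge_endpoints_are_tree_nodes(self, femrep_graph):
        for pop in femrep_graph.populations.values():
            nodes = tree_nodes(pop.path)
            for edge in partial_order_to_adjacency(pop.path, pop.id):
                assert edge.from_loc in nodes and edge.to_loc in nodes


class TestToSimpleGraph:
    def test_idempotent(self, femrep_graph):
        once = to_simple_graph(femrep_graph)
        twice = to_simple_graph(once)
        assert twice.populations == once.populations
        assert twice.adjacency == once.adjacency
        assert twice.dialect == "simple"

    def test_empty_graph_stays_empty(self):
        from neurokg import KnowledgeGraph

        simple = to_simple_graph(KnowledgeGraph())
        assert not simple.populations and not simple.adjacency

    def test_population_without_path_flagged_not_fatal(self):
        from neurokg import KnowledgeGraph, NeuronPopulation

        kg = KnowledgeGraph()
        kg.add_population(
            NeuronPopulation(
                id=Curie.parse("pop:1"),
                label="pathless",
                locations={
                    LocationRole.SOMA: frozenset({Curie.parse("ILX:0000001")}),
                    LocationRole.AXON_TERMINAL: frozenset({Curie.parse("ILX:0000002")}),
                },
            )
        )
        report = TransformReport()
        simple = to_simple_graph(kg, report)
        assert simple.adjacency == {}
        assert report.missing_partial_order == [Curie.parse("pop:1")]

    def test_simple_turtle_round_trip_preserves_populations(self, femrep_graph):
        simple = to_simple_graph(femrep_graph)
        kg2 = read_simple_ttl(write_simple_ttl(simple))
        for pop_id, pop in simple.populations.items():
            got = kg2.populations[pop_id]
            assert got.locations == pop.locations
            assert got.species == pop.species
            assert got.sex == pop.sex
            assert got.phenotypes == pop.phenotypes
            assert got.forward_connections == pop.forward_connections
            assert set(kg2.adjacency[pop_id]) == set(simple.adjacency[pop_id])


class TestDialectEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_axiom_pattern_equals_shortcut_pattern(self, seed):
        """The origin/destination listing computed by walking raw
        equivalent-class axioms equals the one over materialized shortcut
        triples, for every generated graph."""
        kg, _ = generate_graph(GeneratorConfig(n_populations=8, n_entities=40, seed=seed))
        owl_rows = origins_destinations_owl_pattern(graph_to_owl(kg))
        simple_rows = origins_destinations_simple_pattern(write_simple_ttl(kg))
        assert owl_rows == simple_rows
        assert owl_rows  # non-vacuous: every graph has populations
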