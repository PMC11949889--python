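"""Competency queries: organ termination, nerve routing, perturbation,
innervation circuits, summaries, and the open/closed-world filters."""

import pytest

from neurokg import (
    Curie,
    affected_by_perturbation,
    connections_terminating_in,
    connections_via,
    filter_populations,
    graph_from_owl,
    graph_to_owl,
    innervation_circuit,
    load_fixture,
    phenotype_summary,
    read_simple_ttl,
    write_simple_ttl,
)
from neurokg.fixtures import BLADDER_PLANTED, CHAIN_LOCATIONS
from neurokg.queries import LabelLookupError


class TestOrganTermination:
    def test_planted_bladder_populations_recovered_exactly(self, bladder_graph):
        rows = connections_terminating_in(bladder_graph, "urinary bladder")
        assert {r.population for r in rows} == BLADDER_PLANTED

    def test_partonomy_scoping_includes_organ_parts(self, bladder_graph):
        rows = connections_terminating_in(bladder_graph, "urinary bladder")
        neck_rows = [r for r in rows if r.destination.label == "neck of urinary bladder"]
        assert neck_rows, "populations terminating in a bladder part must be returned"

    def test_organ_without_populations_is_empty(self, bladder_graph):
        # the nerve root is an entity no population terminates in
        assert connections_terminating_in(bladder_graph, "nerve") == []

    def test_unresolvable_organ_label_raises(self, bladder_graph):
        with pytest.raises(LabelLookupError):
            connections_terminating_in(bladder_graph, "gallbladder")

    def test_nerve_via_filter_is_a_subset_of_unfiltered(self, bladder_graph):
        strict = connections_terminating_in(bladder_graph, "urinary bladder", True)
        loose = connections_terminating_in(bladder_graph, "urinary bladder", False)
        assert set(strict) <= set(loose)

    def test_rows_are_sorted_and_distinct(self, bladder_graph):
        rows = connections_terminating_in(bladder_graph, "urinary bladder")
        keys = [r.sort_key() for r in rows]
        assert keys == sorted(keys)
        assert len(rows) == len(set(rows))


class TestNerveRouting:
    def test_branch_routed_population_found_under_trunk_label(self, vagus_graph):
        rows = connections_via(vagus_graph, "vagus nerve")
        pops = {r.population.render() for r in rows}
        # vagustoy:2 travels only the internal branch of the superior
        # laryngeal nerve, two partonomy hops below the trunk
        assert "vagustoy:2" in pops

    def test_unrelated_nerve_excluded(self, vagus_graph):
        rows = connections_via(vagus_graph, "vagus nerve")
        assert "vagustoy:4" not in {r.population.render() for r in rows}

    def test_query_by_synonym(self, vagus_graph):
        # the nodose ganglion synonym names a soma structure, not a nerve:
        # no population travels *through* it
        assert connections_via(vagus_graph, "nodose ganglion") == []


class TestPerturbation:
    def test_worked_example_affects_five_structures(self, prostate_graph):
        affected = affected_by_perturbation(prostate_graph, "inferior mesenteric ganglion")
        assert {a.label for a in affected} == {
            "L2 segment of lumbar spinal cord",
            "L3 segment of lumbar spinal cord",
            "L4 segment of lumbar spinal cord",
            "L5 segment of lumbar spinal cord",
            "lumbar splanchnic nerve",
        }

    def test_untouched_structure_affects_nothing(self, prostate_graph):
        assert affected_by_perturbation(prostate_graph, "nerve plexus") == frozenset()

    def test_shared_structure_unions_both_populations(self, femrep_graph):
        affected = {a.label for a in affected_by_perturbation(femrep_graph, "ovarian nerve plexus")}
        # both post-ganglionic populations travel the plexus
        assert "left ovary" in affected and "right ovary" in affected

    def test_symmetry(self, femrep_graph):
        labels = [e.label for e in femrep_graph.entities.values()]
        results = {
            label: {a.curie for a in affected_by_perturbation(femrep_graph, label)}
            for label in labels
        }
        by_label = {e.label: e.curie for e in femrep_graph.entities.values()}
        for la in labels:
            for lb in labels:
                if la == lb:
                    continue
                assert (by_label[lb] in results[la]) == (by_label[la] in results[lb])


class TestInnervationCircuit:
    def test_worked_example_circuit_members(self, femrep_graph):
        rows = innervation_circuit(femrep_graph, "ovary", "Sympathetic Post-Ganglionic phenotype")
        members = {r.population.render() for r in rows}
        assert members == {"femrep:36", "femrep:37", "femrep:40-1"}

    def test_synapses_flag_chain_ganglia_only(self, femrep_graph):
        rows = innervation_circuit(femrep_graph, "ovary", "Sympathetic Post-Ganglionic phenotype")
        synapse_nodes = {r.v2.curie for r in rows if r.is_synapse}
        assert synapse_nodes == CHAIN_LOCATIONS
        # all synapse edges belong to the pre-ganglionic population
        assert {r.population.render() for r in rows if r.is_synapse} == {"femrep:36"}

    def test_post_without_inbound_connection_yields_no_synapses(self, bladder_graph):
        rows = innervation_circuit(bladder_graph, "urinary bladder", "Sympathetic phenotype")
        assert rows and not any(r.is_synapse for r in rows)

    def test_unknown_phenotype_label_is_usage_error(self, femrep_graph):
        with pytest.raises(ValueError, match="unknown autonomic phenotype"):
            innervation_circuit(femrep_graph, "ovary", "Ambidextrous phenotype")

    def test_three_tier_forward_connection_chain_fully_recovered(self):
        """Predecessor traversal is transitive: a chain pre -> mid -> post
        returns all three tiers for the end organ."""
        from neurokg import (
            AnatomicalEntity,
            AnsDivision,
            AnsPhenotype,
            GanglionicOrder,
            KnowledgeGraph,
            LocationRole,
            NeuronPopulation,
            PartialOrderTree,
            PhenotypeAnnotation,
            PrefixRegistry,
        )

        kg = KnowledgeGraph(
            prefixes=PrefixRegistry({"pop": "http://uri.neurokg.org/populations/pop/"})
        )
        organ = Curie.parse("ILX:0000010")
        stops = [Curie.parse(f"ILX:000000{i}") for i in range(1, 5)]
        kg.add_entity(AnatomicalEntity(organ, "tiered organ"))
        for i, s in enumerate(stops):
            kg.add_entity(AnatomicalEntity(s, f"tier stop {i}"))
        specs = [
            ("pop:a", stops[0], stops[1], frozenset({Curie.parse("pop:b")}), GanglionicOrder.PRE_GANGLIONIC, stops[1]),
            ("pop:b", stops[1], stops[2], frozenset({Curie.parse("pop:c")}), GanglionicOrder.PRE_GANGLIONIC, stops[2]),
            ("pop:c", stops[2], stops[3], frozenset(), GanglionicOrder.POST_GANGLIONIC, organ),
        ]
        for pid, soma, _, forward, order, terminal in specs:
            kg.add_population(
                NeuronPopulation(
                    id=Curie.parse(pid),
                    label=pid,
                    locations={
                        LocationRole.SOMA: frozenset({soma}),
                        LocationRole.AXON_TERMINAL: frozenset({terminal}),
                    },
                    path=PartialOrderTree.chain([soma, terminal]),
                    phenotypes=PhenotypeAnnotation(
                        ans=AnsPhenotype(AnsDivision.SYMPATHETIC, order)
                    ),
                    forward_connections=forward,
                )
            )
        rows = innervation_circuit(kg, "tiered organ", "Sympathetic Post-Ganglionic phenotype")
        assert {r.population.render() for r in rows} == {"pop:a", "pop:b", "pop:c"}


class TestDialectAgreement:
    @pytest.mark.parametrize("fixture_name", ["prostate", "femrep", "bladder_toy", "vagus_toy"])
    def test_queries_agree_between_dialect_loads(self, fixture_name):
        owl_kg = graph_from_owl(graph_to_owl(load_fixture(fixture_name)))
        simple_kg = read_simple_ttl(write_simple_ttl(load_fixture(fixture_name)))
        for label in sorted({e.label for e in owl_kg.entities.values()}):
            assert affected_by_perturbation(owl_kg, label) == affected_by_perturbation(
                simple_kg, label
            )
        if fixture_name == "femrep":
            a = innervation_circuit(owl_kg, "ovary", "Sympathetic Post-Ganglionic phenotype")
            b = innervation_circuit(simple_kg, "ovary", "Sympathetic Post-Ganglionic phenotype")
            assert a == b


class TestSexSpeciesFilters:
    def test_sex_closed_world(self, bladder_graph):
        male_view = filter_populations(bladder_graph, sex="male")
        female_view = filter_populations(bladder_graph, sex="female")
        female_specific = Curie.parse("bladder:1")
        male_specific = Curie.parse("bladder:2")
        unsexed = Curie.parse("bladder:5")
        assert female_specific not in male_view and female_specific in female_view
        assert male_specific not in female_view and male_specific in male_view
        assert unsexed in male_view and unsexed in female_view

    def test_sex_closed_world_survives_serialization(self, femrep_graph):
        kg = graph_from_owl(graph_to_owl(femrep_graph))  # all female-specific
        assert filter_populations(kg, sex="male") == frozenset()
        assert filter_populations(kg, sex="female") == frozenset(kg.populations)

    def test_species_open_world(self, bladder_graph):
        rat_view = filter_populations(bladder_graph, species="Rattus norvegicus")
        unassigned_view = filter_populations(bladder_graph, species="unassigned")
        assert rat_view == {Curie.parse(f"bladder:{i}") for i in (1, 2, 3)}
        assert rat_view.isdisjoint(unassigned_view)
        assert rat_view | unassigned_view == frozenset(bladder_graph.populations)


class TestPhenotypeSummary:
    def test_worked_example_ans_row(self, prostate_graph):
        df = phenotype_summary(prostate_graph)
        row = df[(df.dimension == "ANS phenotype") & (df.value == "Sympathetic")]
        assert row.population_count.item() == 1

    def test_empty_graph_is_all_zero(self):
        from neurokg import KnowledgeGraph

        df = phenotype_summary(KnowledgeGraph())
        assert (df.population_count == 0).all()

    def test_species_counts_are_non_exclusive_and_unassigned_complementary(
        self, bladder_graph
    ):
        df = phenotype_summary(bladder_graph)
        species = df[df.dimension == "Species"].set_index("value").population_count
        assert species["Rattus norvegicus"] == 3
        assert species["Unassigned"] == 7
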