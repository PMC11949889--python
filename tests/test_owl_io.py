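"""OWL axiom-dialect serialization: structure, determinism, round trips."""

import pytest
from rdflib import Graph

from neurokg import (
    Curie,
    DialectError,
    graph_from_owl,
    graph_to_owl,
    load_fixture,
    read_ttl,
    write_ttl,
)
from neurokg.fixtures import IMG, L2, L3, L4, L5, LUMBAR_SPLANCHNIC
from neurokg.model import TreeError
from tests.conftest import random_population_graph

P24 = Curie.parse("prostate:24")


@pytest.fixture(scope="module")
def prostate_ttl():
    return graph_to_owl(load_fixture("prostate"))


class TestWriter:
    def test_output_parses_as_turtle(self, prostate_ttl):
        g = Graph()
        g.parse(data=prostate_ttl, format="turtle")
        assert len(g) > 0

    def test_restriction_counts_for_worked_example(self, prostate_ttl):
        # four soma restrictions, one axon, one presynaptic-element,
        # one forward-connection restriction
        assert prostate_ttl.count("ilxtr:hasSomaLocatedIn") == 4
        assert prostate_ttl.count("ilxtr:hasAxonLocatedIn") == 1
        assert prostate_ttl.count("ilxtr:hasAxonPresynapticElementIn") == 1
        assert prostate_ttl.count("ilxtr:hasForwardConnectionPhenotype") == 1

    def test_every_location_sits_in_a_part_of_wrapper(self, prostate_ttl):
        # each locational restriction nests a part-of someValuesFrom
        n_locations = 6  # 4 somata + 1 axon + 1 terminal
        assert prostate_ttl.count("owl:onProperty partOf:") == n_locations

    def test_sex_specific_population_carries_opposite_complement(self, prostate_ttl):
        # male-specific: male restriction plus negated female restriction
        assert "PATO:0000384" in prostate_ttl  # male
        assert "owl:complementOf" in prostate_ttl
        assert "PATO:0000383" in prostate_ttl  # female, inside the complement

    def test_unset_species_emits_no_taxon_restriction(self):
        kg = load_fixture("salivary")  # species deliberately unspecified
        assert "hasInstanceInTaxon" not in graph_to_owl(kg)

    def test_writer_is_byte_deterministic(self):
        a = graph_to_owl(load_fixture("femrep"))
        b = graph_to_owl(load_fixture("femrep"))
        assert a == b

    def test_invalid_population_refused(self):
        from neurokg import LocationRole, NeuronPopulation

        bad = NeuronPopulation(
            id=Curie.parse("pop:1"),
            label="no destination",
            locations={LocationRole.SOMA: frozenset({Curie.parse("ILX:0000001")})},
        )
        with pytest.raises(ValueError, match="MISSING_DESTINATION|no axon-terminal"):
            write_ttl([bad], [])

    def test_label_comment_flag_appends_index(self):
        kg = load_fixture("prostate")
        text = graph_to_owl(kg, emit_label_comments=True)
        assert "# UBERON:0018683  lumbar splanchnic nerve" in text


class TestReader:
    def test_partial_order_tree_reconstructed(self, prostate_ttl):
        result = read_ttl(prostate_ttl)
        (pop,) = [p for p in result.populations if p.id == P24]
        root = pop.path
        assert root.is_root
        # four children rooted at the L5, L2, L3, L4 segments, in document order
        assert [child.node for child in root.children] == [L5, L2, L3, L4]
        assert root.children[0].children[0].node == LUMBAR_SPLANCHNIC
        assert root.children[0].children[0].children[0].node == IMG

    def test_round_trip_identity_on_fixture(self, femrep_graph):
        kg2 = graph_from_owl(graph_to_owl(femrep_graph))
        assert kg2.populations == femrep_graph.populations
        assert kg2.entities == femrep_graph.entities
        assert kg2.population_stubs == femrep_graph.population_stubs

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_identity_on_random_populations(self, seed):
        kg = random_population_graph(seed, n_pops=5)
        kg2 = graph_from_owl(graph_to_owl(kg))
        assert kg2.populations == kg.populations

    def test_non_turtle_input_raises_parse_error(self):
        with pytest.raises(Exception, match="line|Expected|bad"):
            read_ttl("this is { not turtle")

    def test_missing_base_marker_is_dialect_error_naming_population(self, prostate_ttl):
        broken = prostate_ttl.replace("ilxtr:NeuronSparcNlp", "ilxtr:SomethingElse")
        with pytest.raises(DialectError, match="prostate"):
            read_ttl(broken)

    def test_missing_part_of_wrapper_tolerated_with_warning(self):
        text = """
        @prefix ilxtr: <http://uri.interlex.org/tgbugs/uris/readable/> .
        @prefix UBERON: <http://purl.obolibrary.org/obo/UBERON_> .
        @prefix pop: <http://uri.neurokg.org/populations/pop/> .
        @prefix owl: <http://www.w3.org/2002/07/owl#> .
        @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
        pop:1 a owl:Class ;
            rdfs:label "bare filler population" ;
            owl:equivalentClass [ a owl:Class ; owl:intersectionOf (
                ilxtr:NeuronSparcNlp
                [ a owl:Restriction ; owl:onProperty ilxtr:hasSomaLocatedIn ;
                  owl:someValuesFrom UBERON:0000001 ]
                [ a owl:Restriction ; owl:onProperty ilxtr:hasAxonPresynapticElementIn ;
                  owl:someValuesFrom [ a owl:Restriction ;
                      owl:onProperty <http://purl.obolibrary.org/obo/BFO_0000050> ;
                      owl:someValuesFrom UBERON:0000002 ] ]
            ) ] .
        """
        result = read_ttl(text)
        (pop,) = result.populations
        from neurokg import LocationRole

        assert pop.locs(LocationRole.SOMA) == {Curie.parse("UBERON:0000001")}
        assert any("part-of wrapper" in w for w in result.warnings)

    def test_malformed_partial_order_collection_rejected(self):
        text = """
        @prefix ilxtr: <http://uri.interlex.org/tgbugs/uris/readable/> .
        @prefix pop: <http://uri.neurokg.org/populations/pop/> .
        @prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
        @prefix owl: <http://www.w3.org/2002/07/owl#> .
        @prefix UBERON: <http://purl.obolibrary.org/obo/UBERON_> .
        pop:1 owl:equivalentClass [ a owl:Class ; owl:intersectionOf (
                  ilxtr:NeuronSparcNlp
                  [ a owl:Restriction ; owl:onProperty ilxtr:hasSomaLocatedIn ;
                    owl:someValuesFrom UBERON:0000001 ]
                  [ a owl:Restriction ; owl:onProperty ilxtr:hasAxonPresynapticElementIn ;
                    owl:someValuesFrom UBERON:0000002 ]
              ) ] ;
              ilxtr:neuronPartialOrder [ rdf:first "blank" ] .
        """
        with pytest.raises(TreeError):
            read_ttl(text)

    def test_read_iterates_as_populations_entities_pair(self, prostate_ttl):
        populations, entities = read_ttl(prostate_ttl)
        assert {p.id.render() for p in populations} == {"prostate:24"}
        assert any(e.label == "inferior mesenteric ganglion" for e in entities)
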