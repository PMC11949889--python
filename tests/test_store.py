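"""Closure services: ancestors, label resolution, nerve-likeness."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from neurokg import AnatomicalEntity, Curie, KnowledgeGraph
from neurokg.fixtures import (
    BLADDER,
    BLADDER_NECK,
    IMG,
    LUMBAR_SPLANCHNIC,
    NODOSE,
    OVARIAN_PLEXUS,
    VAGUS,
)


def chain_graph(*labels):
    """a part_of b part_of c ... for quick closure checks."""
    kg = KnowledgeGraph()
    curies = [Curie("ILX", f"2{i:06d}") for i in range(len(labels))]
    for i, (c, label) in enumerate(zip(curies, labels)):
        parents = frozenset({curies[i + 1]}) if i + 1 < len(curies) else frozenset()
        kg.add_entity(AnatomicalEntity(c, label, part_of=parents))
    return kg, curies


class TestAncestors:
    def test_part_of_chain(self):
        kg, (a, b, c) = chain_graph("a", "b", "c")
        assert kg.ancestors(a, {"part_of"}) == {a, b, c}

    def test_reflexive_for_isolated_node(self):
        kg, (a,) = chain_graph("a")
        assert kg.ancestors(a, {"part_of", "subclass_of", "supplies_to"}) == {a}

    def test_fixture_partonomy_reaches_bladder(self, bladder_graph):
        assert BLADDER in bladder_graph.ancestors(BLADDER_NECK, {"part_of"})

    def test_unknown_relation_rejected(self):
        kg, (a,) = chain_graph("a")
        with pytest.raises(ValueError, match="unknown relations"):
            kg.ancestors(a, {"sibling_of"})

    def test_cycle_terminates(self):
        kg = KnowledgeGraph()
        a, b = Curie.parse("ILX:0000001"), Curie.parse("ILX:0000002")
        kg.add_entity(AnatomicalEntity(a, "a", part_of=frozenset({b})))
        kg.add_entity(AnatomicalEntity(b, "b", part_of=frozenset({a})))
        assert kg.ancestors(a, {"part_of"}) == {a, b}

    def test_supplies_to_is_a_closure_relation(self):
        kg, (a, b) = chain_graph("a", "b")
        organ = Curie.parse("ILX:0009999")
        kg.add_entity(AnatomicalEntity(organ, "organ"))
        kg.add_supplies_to(b, organ)
        assert organ in kg.ancestors(a, {"part_of", "supplies_to"})
        assert organ not in kg.ancestors(a, {"part_of"})


def brute_force_closure(edges, start):
    """Independent oracle: iterate edge expansion to a fixpoint."""
    reached = {start}
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            if u in reached and v not in reached:
                reached.add(v)
                changed = True
    return frozenset(reached)


class TestClosureOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 200)
        curies = [Curie("ILX", f"3{i:06d}") for i in range(n)]
        edges = set()
        kg = KnowledgeGraph()
        for i, c in enumerate(curies):
            parents = frozenset(
                rng.sample(curies[:i], min(i, rng.randint(0, 2)))
            )
            kg.add_entity(AnatomicalEntity(c, f"n{i}", part_of=parents))
            edges |= {(c, p) for p in parents}
        for start in rng.sample(curies, min(n, 12)):
            assert kg.ancestors(start, {"part_of"}) == brute_force_closure(edges, start)

    def test_monotone_under_edge_addition(self):
        rng = random.Random(42)
        kg, curies = chain_graph(*[f"n{i}" for i in range(10)])
        before = {c: kg.ancestors(c, {"part_of"}) for c in curies}
        extra_child, extra_parent = curies[2], curies[8]
        ent = kg.entities[extra_child]
        kg.add_entity(
            AnatomicalEntity(
                ent.curie, ent.label, part_of=ent.part_of | {extra_parent}
            )
        )
        for c in curies:
            assert before[c] <= kg.ancestors(c, {"part_of"})


class TestLabelResolution:
    def test_label_lookup_is_case_insensitive(self, vagus_graph):
        assert vagus_graph.resolve_label("Vagus Nerve") == {VAGUS}

    def test_synonym_resolves_to_same_entity(self, vagus_graph):
        assert vagus_graph.resolve_label("nodose ganglion") == {NODOSE}
        assert vagus_graph.resolve_label("inferior vagus X ganglion") == {NODOSE}

    def test_unknown_label_is_empty(self, vagus_graph):
        assert vagus_graph.resolve_label("no-such-structure") == frozenset()

    @settings(max_examples=30, derandomize=True)
    @given(st.permutations(list("vagus nerve")))
    def test_stable_under_case_permutation(self, chars):
        kg = KnowledgeGraph()
        c = Curie.parse("ILX:0000001")
        kg.add_entity(AnatomicalEntity(c, "vagus nerve"))
        mixed = "".join(
            ch.upper() if i % 2 else ch for i, ch in enumerate("".join(chars))
        )
        # any case variant of any permutation of the same letters either
        # matches exactly the one label or nothing
        expected = {c} if mixed.lower() == "vagus nerve" else frozenset()
        assert kg.resolve_label(mixed) == expected


class TestNerveLike:
    def test_fixture_nerve_subclass(self, prostate_graph):
        assert prostate_graph.is_nerve_like(LUMBAR_SPLANCHNIC)

    def test_ganglion_is_not_nerve_like(self, prostate_graph):
        assert not prostate_graph.is_nerve_like(IMG)

    def test_nerve_plexus_subclass(self, femrep_graph):
        assert femrep_graph.is_nerve_like(OVARIAN_PLEXUS)

    def test_unknown_curie_raises(self, prostate_graph):
        with pytest.raises(KeyError):
            prostate_graph.is_nerve_like(Curie.parse("ILX:9999999"))
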