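"""Motif enumeration, canonical labeling and census correctness."""

import math

import numpy as np
import pytest

from oracles import (
    brute_canonical_key,
    brute_census,
    brute_connected_ksets,
    random_typed_graph,
    subgraph_parts,
)
from tnmca.motif_census import (
    build_census,
    canonical_form,
    enumerate_connected_subgraphs,
    is_valid_tnm,
    iter_motif_instances,
    tnm_score,
)
from tnmca.typed_graph import TypedGraph, UNTYPED


class TestEnumeration:
    def test_triangle_single_set(self, triangle_graph):
        sets = list(enumerate_connected_subgraphs(triangle_graph, 3))
        assert sets == [frozenset({"drug1", "gene1", "disease1"})]

    def test_path_is_connected_set(self, path_graph):
        assert list(enumerate_connected_subgraphs(path_graph, 3)) == [
            frozenset({"a", "b", "c"})
        ]

    def test_four_cycle_has_four_triples(self, four_cycle_graph):
        assert len(list(enumerate_connected_subgraphs(four_cycle_graph, 3))) == 4

    def test_k_below_three_rejected(self, triangle_graph):
        with pytest.raises(ValueError):
            list(enumerate_connected_subgraphs(triangle_graph, 2))

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_exhaustive_subsets(self, k):
        for seed in range(10):
            g = random_typed_graph(np.random.default_rng(seed), 10, edge_prob=0.25)
            got = list(enumerate_connected_subgraphs(g, k))
            assert len(got) == len(set(got)), "duplicate node sets emitted"
            assert set(got) == brute_connected_ksets(g, k)


class TestValidity:
    def test_typed_triangle_valid(self, triangle_graph):
        assert is_valid_tnm(triangle_graph, {"drug1", "gene1", "disease1"})

    def test_path_endpoints_fail_degree(self, path_graph):
        assert not is_valid_tnm(path_graph, {"a", "b", "c"})

    def test_four_cycle_valid(self, four_cycle_graph):
        assert is_valid_tnm(
            four_cycle_graph, {"drug1", "pathway1", "gene1", "disease1"}
        )

    def test_distinct_type_minimum(self):
        g = TypedGraph()
        for name in ("a", "b"):
            g.add_node(name, "gene")
        g.add_node("c", "disease")
        g.add_edge("a", "b", UNTYPED)
        g.add_edge("b", "c", UNTYPED)
        g.add_edge("a", "c", UNTYPED)
        assert not is_valid_tnm(g, {"a", "b", "c"}, min_distinct_types=3)
        assert is_valid_tnm(g, {"a", "b", "c"}, min_distinct_types=2)


class TestCanonicalForm:
    def test_relabeling_invariance(self):
        def build(names):
            g = TypedGraph()
            g.add_node(names[0], "chemical")
            g.add_node(names[1], "gene")
            g.add_node(names[2], "disease")
            g.add_edge(names[0], names[1], "increases")
            g.add_edge(names[1], names[2], "marker")
            g.add_edge(names[0], names[2], "therapeutic")
            return g

        g1 = build(["x", "y", "z"])
        g2 = build(["zz", "aa", "mm"])
        key1 = canonical_form(g1, set(g1.nodes())).canonical_key
        key2 = canonical_form(g2, set(g2.nodes())).canonical_key
        assert key1 == key2

    def test_different_type_multisets_differ(self):
        def triangle(types):
            g = TypedGraph()
            for name, t in zip("abc", types):
                g.add_node(name, t)
            for u, v in (("a", "b"), ("b", "c"), ("a", "c")):
                g.add_edge(u, v, UNTYPED)
            return g

        t1 = triangle(["A", "B", "C"])
        t2 = triangle(["A", "B", "B"])
        k1 = canonical_form(t1, set(t1.nodes())).canonical_key
        k2 = canonical_form(t2, set(t2.nodes()), min_distinct_types=2).canonical_key
        assert k1 != k2

    def test_invalid_input_rejected(self, path_graph):
        with pytest.raises(ValueError):
            canonical_form(path_graph, {"a", "b", "c"})

    def test_agrees_with_full_permutation_search(self, rng):
        # implementation minimizes over type-sorted orderings only; the
        # oracle minimizes over all k! permutations
        for seed in range(10):
            g = random_typed_graph(np.random.default_rng(seed), 9, edge_prob=0.4)
            for nodes in brute_connected_ksets(g, 4):
                if not is_valid_tnm(g, nodes, min_distinct_types=2):
                    continue
                got = canonical_form(g, nodes, min_distinct_types=2).canonical_key
                assert got == brute_canonical_key(*subgraph_parts(g, nodes))


class TestCensus:
    def test_single_triangle(self, triangle_graph):
        census = build_census(triangle_graph, 3)
        assert list(census.frequencies.values()) == [1]
        assert census.total == 1

    def test_two_patterns_with_multiplicity(self):
        # two disjoint copies of a typed triangle P plus one copy of a
        # differently-typed triangle Q
        g = TypedGraph()
        for i in (1, 2):
            g.add_node(f"c{i}", "chemical")
            g.add_node(f"g{i}", "gene")
            g.add_node(f"d{i}", "disease")
            g.add_edge(f"c{i}", f"g{i}", "increases")
            g.add_edge(f"g{i}", f"d{i}", "marker")
            g.add_edge(f"c{i}", f"d{i}", "therapeutic")
        g.add_node("c3", "chemical")
        g.add_node("p3", "pathway")
        g.add_node("d3", "disease")
        g.add_edge("c3", "p3", UNTYPED)
        g.add_edge("p3", "d3", UNTYPED)
        g.add_edge("c3", "d3", "therapeutic")
        census = build_census(g, 3)
        assert sorted(census.frequencies.values()) == [1, 2]
        assert census.total == 3
        assert census.frequencies == brute_census(g, 3)

    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_oracle(self, k):
        for seed in range(8):
            g = random_typed_graph(np.random.default_rng(100 + seed), 11, edge_prob=0.3)
            assert build_census(g, k).frequencies == brute_census(g, k)

    def test_fast_instance_iterator_matches_filtered_enumeration(self, rng):
        for seed in range(5):
            g = random_typed_graph(np.random.default_rng(200 + seed), 12, edge_prob=0.3)
            for k in (3, 4):
                fast = set(iter_motif_instances(g, k))
                slow = {
                    s
                    for s in enumerate_connected_subgraphs(g, k)
                    if is_valid_tnm(g, s)
                }
                assert fast == slow


class TestScores:
    def test_single_pattern_scores_one(self, triangle_graph):
        census = build_census(triangle_graph, 3)
        (key,) = census.frequencies
        assert tnm_score(census, key) == 1.0

    def test_forced_fraction(self):
        census = build_census(triangle_fixture_with_copies(2, 1), 3)
        by_freq = sorted(census.frequencies.items(), key=lambda kv: -kv[1])
        assert tnm_score(census, by_freq[0][0]) == pytest.approx(2 / 3)

    def test_scores_sum_to_one(self, rng):
        for seed in range(5):
            g = random_typed_graph(np.random.default_rng(300 + seed), 12, edge_prob=0.35)
            census = build_census(g, 3)
            if not census.frequencies:
                continue
            scores = [tnm_score(census, key) for key in census.frequencies]
            assert all(0 < s <= 1 for s in scores)
            assert math.isclose(sum(scores), 1.0)

    def test_unknown_key_raises(self, triangle_graph):
        census = build_census(triangle_graph, 3)
        with pytest.raises(KeyError):
            tnm_score(census, "no-such-key")


def triangle_fixture_with_copies(n_p: int, n_q: int) -> TypedGraph:
    """n_p chemical-gene-disease triangles and n_q chemical-pathway-disease ones."""
    g = TypedGraph()
    idx = 0
    for _ in range(n_p):
        idx += 1
        g.add_node(f"c{idx}", "chemical")
        g.add_node(f"g{idx}", "gene")
        g.add_node(f"d{idx}", "disease")
        g.add_edge(f"c{idx}", f"g{idx}", "increases")
        g.add_edge(f"g{idx}", f"d{idx}", "marker")
        g.add_edge(f"c{idx}", f"d{idx}", "therapeutic")
    for _ in range(n_q):
        idx += 1
        g.add_node(f"c{idx}", "chemical")
        g.add_node(f"p{idx}", "pathway")
        g.add_node(f"d{idx}", "disease")
        g.add_edge(f"c{idx}", f"p{idx}", UNTYPED)
        g.add_edge(f"p{idx}", f"d{idx}", UNTYPED)
        g.add_edge(f"c{idx}", f"d{idx}", "therapeutic")
    return g
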