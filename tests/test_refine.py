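"""Good-split-graphs, disconnected bipartitions, and split refinements."""

import pytest

from gtcons.aux_graph import build_aux_graph, maximal_topological_sort
from gtcons.gene_tree import read_labeled_gene_tree
from gtcons.refine import (
    apply_split_refinement,
    disconnected_bipartition,
    find_good_split,
    good_split_graph,
)
from gtcons.tree import star_tree
from gtcons.triplets import informative_triplets

from oracles import is_good_split


def resolved_binary(T):
    """Binary internal vertices with at least one internal child."""
    return sum(
        1
        for v in T.vertices
        if len(T.children(v)) == 2
        and any(not T.is_leaf(c) for c in T.children(v))
    )


def graph_at_star(gt):
    S = star_tree(gt.species())
    Q = maximal_topological_sort(build_aux_graph(gt, S))
    return good_split_graph(gt, S, Q, S.root), S


class TestGoodSplitGraph:
    def test_fig1_star_two_edges(self, fig1):
        G, _ = graph_at_star(fig1[0])
        assert G.vertices == {"A", "B", "C", "D"}
        assert sorted(tuple(sorted(e)) for e in G.graph.edges()) == [
            ("A", "B"),
            ("A", "C"),
        ]

    def test_fig1_edge_conditions_are_sound(self, fig1):
        G, _ = graph_at_star(fig1[0])
        for a, b in G.graph.edges():
            assert G.edge_conditions(a, b) <= {"C1", "C2", "C3", "C4"}
            assert G.edge_conditions(a, b)

    def test_incompatible_toy_connected(self, incompatible_toy):
        G, _ = graph_at_star(incompatible_toy)
        assert {tuple(sorted(e)) for e in G.graph.edges()} >= {
            ("A", "B"),
            ("B", "C"),
        }
        assert disconnected_bipartition(G) is None

    def test_plain_speciation_no_edges(self):
        gt = read_labeled_gene_tree(
            "(a[&&NHX:S=A],b[&&NHX:S=B],c[&&NHX:S=C])[&&NHX:ev=S];"
        )
        G, _ = graph_at_star(gt)
        assert G.graph.number_of_edges() == 0

    def test_non_cherry_is_error(self, fig1):
        gt, _, S_bin = fig1
        Q = maximal_topological_sort(build_aux_graph(gt, S_bin))
        with pytest.raises(ValueError):
            good_split_graph(gt, S_bin, Q, S_bin.root)


class TestDisconnectedBipartition:
    def test_edgeless(self):
        gt = read_labeled_gene_tree(
            "(a[&&NHX:S=A],b[&&NHX:S=B])[&&NHX:ev=D];"
        )
        G, _ = graph_at_star(gt)
        assert disconnected_bipartition(G) == ({"A"}, {"B"})

    def test_fig1_splits_off_D(self, fig1):
        G, _ = graph_at_star(fig1[0])
        assert disconnected_bipartition(G) == ({"A", "B", "C"}, {"D"})


class TestApplySplitRefinement:
    def test_star_to_almost_binary(self):
        S = star_tree({"A", "B", "C", "D"})
        S2 = apply_split_refinement(S, S.root, {"A", "B", "C"}, {"D"})
        assert S2.to_newick() == "((A,B,C),D);"

    def test_two_leaf_star_unchanged(self):
        S = star_tree({"A", "B"})
        assert apply_split_refinement(S, S.root, {"A"}, {"B"}).same_topology(S)

    def test_adds_exactly_one_resolved_binary_vertex(self):
        # a split turns exactly one cherry into a resolved binary vertex
        # (the new blocks are cherries or leaves, still to be refined)
        S = star_tree({"A", "B", "C", "D", "E"})
        S2 = apply_split_refinement(S, S.root, {"A", "B"}, {"C", "D", "E"})
        assert resolved_binary(S2) == resolved_binary(S) + 1
        assert S2.is_almost_binary()

    def test_bad_partition_is_error(self):
        S = star_tree({"A", "B", "C"})
        with pytest.raises(ValueError):
            apply_split_refinement(S, S.root, {"A", "B", "C"}, set())
        with pytest.raises(ValueError):
            apply_split_refinement(S, S.root, {"A"}, {"B"})


class TestFindGoodSplit:
    def test_fig1_run(self, fig1):
        gt, _, S_bin = fig1
        S1 = star_tree(gt.species())
        x, A, B = find_good_split(gt, S1)
        assert (A, B) == ({"A", "B", "C"}, {"D"})
        S2 = apply_split_refinement(S1, x, A, B)
        assert S2.to_newick() == "((A,B,C),D);"
        # S2 has a unique non-binary cherry; resolving it yields the
        # binary tree from the worked example
        x2, A2, B2 = find_good_split(gt, S2)
        S3 = apply_split_refinement(S2, x2, A2, B2)
        assert S3.same_topology(S_bin)

    def test_incompatible_toy_has_none(self, incompatible_toy):
        S = star_tree(incompatible_toy.species())
        assert find_good_split(incompatible_toy, S) is None

    def test_alternative_resolution_is_not_good(self, fig1):
        # resolving the {A,B,C} cherry of ((A,B,C),D) as (A,C)|(B) is a
        # split refinement that agrees with the triplets but whose cherry
        # keeps an unsorted in-neighbor, so it is not good
        gt, S_lr, _ = fig1
        x = next(v for v in S_lr.cherries() if len(S_lr.children(v)) == 3)
        R = informative_triplets(gt)
        assert apply_split_refinement(S_lr, x, {"A", "C"}, {"B"}).agrees(R)
        assert not is_good_split(gt, S_lr, x, {"A", "C"}, {"B"})
        assert not is_good_split(gt, S_lr, x, {"B", "C"}, {"A"})
        assert is_good_split(gt, S_lr, x, {"A", "B"}, {"C"})

    def test_emitted_splits_are_good_and_make_progress(self, small_batch):
        for gt, _ in small_batch[:25]:
            S = star_tree(gt.species())
            R = informative_triplets(gt)
            while not S.is_binary():
                found = find_good_split(gt, S, R=R)
                if found is None:
                    break
                x, A, B = found
                assert is_good_split(gt, S, x, A, B)
                before = maximal_topological_sort(build_aux_graph(gt, S)).members
                S = apply_split_refinement(S, x, A, B)
                after = maximal_topological_sort(build_aux_graph(gt, S)).members
                assert before < after  # strict growth of M(Q)
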