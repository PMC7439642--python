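"""Core rooted-tree machinery: parsing, LCA, triplets, surgery."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtcons.tree import ParseError, RootedTree, Triplet, read_newick, star_tree

from oracles import displayed_triplets_via_restrict


def random_tree(rng: random.Random, n_leaves: int) -> RootedTree:
    """Random topology by repeatedly joining 1-3 subtrees."""
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = list(labels)
    children = {}
    counter = 0
    while len(nodes) > 1:
        k = min(len(nodes), rng.choice([2, 2, 2, 3]))
        picks = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        vid = f"v{counter}"
        counter += 1
        children[vid] = picks
        nodes.append(vid)
    return RootedTree(nodes[0], children, {lab: lab for lab in labels})


class TestNewick:
    def test_star(self):
        t = read_newick("(A,B,C);")
        assert t.leaf_labels() == {"A", "B", "C"}
        internal = [v for v in t.vertices if not t.is_leaf(v)]
        assert len(internal) == 1
        assert t.displayed_triplets() == set()

    def test_resolved(self):
        t = read_newick("((A,B),C);")
        assert t.displayed_triplets() == {Triplet.of("A", "B", "C")}

    def test_almost_binary(self):
        t = read_newick("((A,B,C),D);")
        assert len(t.children(t.root)) == 2
        assert t.is_almost_binary() and not t.is_binary()

    @pytest.mark.parametrize(
        "bad", ["((A,B),C", "(A,,B);", "(A,B),C);", "(A,A);", ";", "(A,(B);"]
    )
    def test_parse_errors(self, bad):
        with pytest.raises(ParseError):
            read_newick(bad)

    def test_round_trip_many_random_trees(self):
        rng = random.Random(42)
        for _ in range(1000):
            t = random_tree(rng, rng.randint(2, 14))
            assert read_newick(t.to_newick()).same_topology(t)

    def test_branch_lengths_parsed_and_ignored(self):
        t = read_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        assert t.displayed_triplets() == {Triplet.of("A", "B", "C")}


class TestLca:
    def test_singleton_is_identity(self):
        t = read_newick("((A,B),C);")
        leaf = t.leaf_by_label("A")
        assert t.lca([leaf]) == leaf

    def test_pair_and_root(self):
        t = read_newick("((A,B),C);")
        a, b = t.leaf_by_label("A"), t.leaf_by_label("B")
        assert t.lca([a, b]) == t.parent[a] == t.parent[b]
        assert t.lca(t.leaves()) == t.root

    def test_errors(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            t.lca([])
        with pytest.raises(ValueError):
            t.lca(["nope"])


class TestTriplets:
    def test_binary_tree_has_n_choose_3(self):
        rng = random.Random(1)
        for _ in range(20):
            n = rng.randint(3, 8)
            labels = [f"L{i}" for i in range(n)]
            nodes = list(labels)
            children = {}
            c = 0
            while len(nodes) > 1:
                x = nodes.pop(rng.randrange(len(nodes)))
                y = nodes.pop(rng.randrange(len(nodes)))
                children[f"v{c}"] = [x, y]
                nodes.append(f"v{c}")
                c += 1
            t = RootedTree(nodes[0], children, {lab: lab for lab in labels})
            assert len(t.displayed_triplets()) == n * (n - 1) * (n - 2) // 6

    def test_matches_restriction_oracle(self):
        rng = random.Random(7)
        for _ in range(30):
            t = random_tree(rng, rng.randint(3, 8))
            assert t.displayed_triplets() == displayed_triplets_via_restrict(t)

    def test_agree_weaker_than_display(self):
        star = read_newick("(A,B,C);")
        R = {Triplet.of("A", "B", "C"), Triplet.of("B", "C", "A")}
        assert star.agrees(R)  # agreement despite R being incompatible
        t = read_newick("((A,B),C);")
        assert not t.agrees({Triplet.of("A", "C", "B")})
        assert t.agrees(set())

    def test_agree_unknown_label_is_error(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            t.agrees({Triplet.of("A", "B", "Z")})


class TestExtension:
    def test_singleton_subset_is_noop(self):
        t = star_tree({"A", "B", "C", "D"})
        assert t.apply_extension(t.root, ["A"]).same_topology(t)

    def test_pair_subset(self):
        t = star_tree({"A", "B", "C", "D"})
        t2 = t.apply_extension(t.root, ["A", "B"])
        assert t2.to_newick() == "((A,B),C,D);"

    def test_counts_and_leaves_preserved(self):
        rng = random.Random(3)
        for _ in range(50):
            t = random_tree(rng, rng.randint(4, 10))
            wide = [v for v in t.vertices if len(t.children(v)) >= 3]
            if not wide:
                continue
            x = rng.choice(sorted(wide))
            ch = list(t.children(x))
            k = rng.randint(2, len(ch) - 1)
            sub = rng.sample(ch, k)
            t2 = t.apply_extension(x, sub)
            assert t2.leaf_labels() == t.leaf_labels()
            n_int = sum(1 for v in t.vertices if not t.is_leaf(v))
            n_int2 = sum(1 for v in t2.vertices if not t2.is_leaf(v))
            assert n_int2 == n_int + 1

    def test_errors(self):
        t = star_tree({"A", "B", "C", "D"})
        with pytest.raises(ValueError):
            t.apply_extension(t.root, ["A", "B", "C", "D"])  # not strict
        with pytest.raises(ValueError):
            t.apply_extension(t.root, ["A", "Z"])  # not a child


class TestRestrict:
    def test_identity(self):
        t = read_newick("(((A,B),C),D);")
        assert t.restrict(t.leaf_labels()).same_topology(t)

    def test_two_leaves(self):
        t = read_newick("((A,B),(C,D));")
        assert t.restrict({"A", "C"}).to_newick() == "(A,C);"

    def test_suppression(self):
        t = read_newick("(((A,B),C),D);")
        assert t.restrict({"A", "B", "D"}).to_newick() == "((A,B),D);"

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_restriction_preserves_triplets(self, seed):
        rng = random.Random(seed)
        t = random_tree(rng, rng.randint(4, 9))
        labels = sorted(t.leaf_labels())
        X = set(rng.sample(labels, rng.randint(2, len(labels) - 1)))
        sub = t.restrict(X)
        assert sub.leaf_labels() == X
        expect = {
            tr for tr in t.displayed_triplets() if {tr.a, tr.b, tr.c} <= X
        }
        assert sub.displayed_triplets() == expect
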