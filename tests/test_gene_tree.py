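"""Event-labeled gene trees: NHX I/O, observability axioms, transfer forest."""

import pytest

from gtcons.gene_tree import (
    DUPLICATION,
    FormatError,
    SPECIATION,
    TRANSFER,
    EventLabeledGeneTree,
    read_labeled_gene_tree,
    read_species_map,
    transfer_forest,
    write_labeled_gene_tree,
)
from gtcons.tree import RootedTree

from conftest import simulated_batch


class TestReader:
    def test_minimal_speciation(self):
        gt = read_labeled_gene_tree(
            "(a[&&NHX:S=A],b[&&NHX:S=B])[&&NHX:ev=S];"
        )
        assert gt.event[gt.tree.root] == SPECIATION
        assert gt.sigma == {"a": "A", "b": "B"}
        assert gt.transfer_edges == set()

    def test_transfer_toy(self, transfer_toy):
        assert len(transfer_toy.transfer_edges) == 1
        (x, y) = next(iter(transfer_toy.transfer_edges))
        assert transfer_toy.event[x] == TRANSFER
        assert transfer_toy.tree.leaf_label[y] == "c"

    def test_species_map_table(self):
        gt = read_labeled_gene_tree(
            "(a,b)[&&NHX:ev=S];", species_map={"a": "A", "b": "B"}
        )
        assert gt.sigma == {"a": "A", "b": "B"}

    def test_read_species_map(self):
        assert read_species_map("g1\tX\ng2\tY\n") == {"g1": "X", "g2": "Y"}
        with pytest.raises(FormatError):
            read_species_map("only-one-column\n")

    def test_missing_event_tag(self):
        with pytest.raises(FormatError):
            read_labeled_gene_tree("(a[&&NHX:S=A],b[&&NHX:S=B]);")

    def test_missing_species(self):
        with pytest.raises(FormatError):
            read_labeled_gene_tree("(a[&&NHX:S=A],b)[&&NHX:ev=S];")

    def test_transfer_flag_under_nontransfer_tail(self):
        with pytest.raises(FormatError):
            read_labeled_gene_tree(
                "(a[&&NHX:S=A],b[&&NHX:S=B:xfer=1])[&&NHX:ev=S];"
            )

    def test_transfer_vertex_without_transfer_edge_parses(self):
        # accepted by the reader; rejected later by the O2 validator
        gt = read_labeled_gene_tree(
            "(a[&&NHX:S=A],b[&&NHX:S=B])[&&NHX:ev=T];"
        )
        assert any(v.startswith("O2") for v in gt.validate_observability())

    def test_round_trip(self, fig1):
        gt, _, _ = fig1
        again = read_labeled_gene_tree(write_labeled_gene_tree(gt))
        assert again.tree.same_topology(gt.tree)
        assert sorted(again.sigma.values()) == sorted(gt.sigma.values())
        assert len(again.transfer_edges) == len(gt.transfer_edges)


class TestValidation:
    def test_fig1_is_valid(self, fig1):
        assert fig1[0].validate_observability() == []

    def test_out_degree_one(self):
        tree = RootedTree("r", {"r": ["m"], "m": ["a", "b"]}, {"a": "a", "b": "b"})
        gt = EventLabeledGeneTree(
            tree, {"r": SPECIATION, "m": SPECIATION}, set(), {"a": "A", "b": "B"}
        )
        assert any(v.startswith("O1") for v in gt.validate_observability())

    def test_speciation_children_share_species(self):
        gt = read_labeled_gene_tree(
            "((a1[&&NHX:S=A],b[&&NHX:S=B])[&&NHX:ev=S],a2[&&NHX:S=A])[&&NHX:ev=S];"
        )
        assert any(v.startswith("O3a") for v in gt.validate_observability())

    def test_transfer_endpoints_share_species(self):
        gt = read_labeled_gene_tree(
            "(a1[&&NHX:S=A],a2[&&NHX:S=A:xfer=1])[&&NHX:ev=T];"
        )
        assert any(v.startswith("O3b") for v in gt.validate_observability())

    def test_simulated_instances_are_valid(self, small_batch):
        for gt, _ in small_batch:
            assert gt.validate_observability() == []


class TestForest:
    def test_no_transfers_single_component(self, incompatible_toy):
        tf = transfer_forest(incompatible_toy)
        assert len(tf.components) == 1
        assert tf.components[0].same_topology(incompatible_toy.tree)

    def test_transfer_toy_components(self, transfer_toy):
        tf = transfer_forest(transfer_toy)
        assert len(tf.components) == 2
        leaf_sets = sorted(sorted(c.leaf_labels()) for c in tf.components)
        assert leaf_sets == [["a", "b"], ["c"]]

    def test_component_count_and_partition(self, small_batch):
        for gt, _ in small_batch:
            tf = transfer_forest(gt)
            assert len(tf.components) == len(gt.transfer_edges) + 1
            all_leaves = sorted(
                lab for c in tf.components for lab in c.leaf_labels()
            )
            assert all_leaves == sorted(gt.tree.leaf_labels())

    def test_component_count_many_more(self):
        # higher transfer pressure, many components
        for gt, _ in simulated_batch(
            40, 5200, n_species=6, transfer_rate=0.8, loss_rate=0.2
        ):
            tf = transfer_forest(gt)
            assert len(tf.components) == len(gt.transfer_edges) + 1


class TestSigmaForest:
    def test_leaf(self, transfer_toy):
        leaf = transfer_toy.tree.leaf_by_label("a")
        assert transfer_toy.sigma_forest(leaf) == {"A"}

    def test_transfer_toy_root_excludes_recipient(self, transfer_toy):
        assert transfer_toy.sigma_forest(transfer_toy.tree.root) == {"A", "B"}

    def test_union_over_nontransfer_children(self, small_batch):
        for gt, _ in small_batch:
            for v in gt.tree.vertices:
                if gt.tree.is_leaf(v):
                    assert gt.sigma_forest(v) == {gt.sigma[v]}
                    continue
                expect = frozenset()
                for c in gt.tree.children(v):
                    if (v, c) not in gt.transfer_edges:
                        expect |= gt.sigma_forest(c)
                assert gt.sigma_forest(v) == expect

    def test_nonempty_everywhere(self, small_batch):
        for gt, _ in small_batch:
            assert all(gt.sigma_forest(v) for v in gt.tree.vertices)
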