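"""Informative species triplets R(T;t,sigma) of an event-labeled gene tree.

A species tree can be reconciled with the gene tree exactly when this
triplet set is compatible, which makes R(T;t,sigma) the central data for
species-tree construction.  A triplet sigma(a)sigma(b)|sigma(c) (species
pairwise distinct) is informative when either

* ab|c is displayed inside one component of the transfer-free forest and
  the component-lca of {a,b,c} is a speciation, or
* a, b lie below one endpoint and c below the other endpoint of some
  transfer edge, within the transfer-free forest (both orientations).

The set is materialized explicitly; it can reach Theta(n^3) triplets and
that is unavoidable for this representation.
"""

from __future__ import annotations

from itertools import combinations

from .gene_tree import SPECIATION, EventLabeledGeneTree
from .tree import Triplet


def speciation_triplets(gt: EventLabeledGeneTree) -> set[Triplet]:
    """Triplets forced by speciation vertices of the transfer-free forest.

    For a speciation v with children c_i, c_j (i != j) in the forest, any
    species pair drawn from sigma_forest(c_i) against a third species from
    sigma_forest(c_j) is informative: the pair's forest-lca lies strictly
    below v while v is the forest-lca of all three leaves.
    """
    out: set[Triplet] = set()
    tree = gt.tree
    for v in tree.preorder():
        if tree.is_leaf(v) or gt.event[v] != SPECIATION:
            continue
        # speciation vertices have no transfer out-edges, but guard anyway
        kids = [c for c in tree.children(v) if (v, c) not in gt.transfer_edges]
        kid_species = [gt.sigma_forest(c) for c in kids]
        for i, si in enumerate(kid_species):
            for j, sj in enumerate(kid_species):
                if i == j:
                    continue
                for sa, sb in combinations(sorted(si), 2):
                    for sc in sj:
                        if sc != sa and sc != sb:
                            out.add(Triplet.of(sa, sb, sc))
    return out


def transfer_triplets(gt: EventLabeledGeneTree) -> set[Triplet]:
    """Triplets forced by transfer edges.

    For a transfer edge (x, y), the donor-side species pair must have
    diverged from every recipient-side species before the transfer could
    happen between coexisting lineages -- and symmetrically.
    """
    out: set[Triplet] = set()
    for (x, y) in gt.transfer_edges:
        side_x = sorted(gt.sigma_forest(x))
        side_y = sorted(gt.sigma_forest(y))
        for pair_side, single_side in ((side_x, side_y), (side_y, side_x)):
            for sa, sb in combinations(pair_side, 2):
                for sc in single_side:
                    if sc != sa and sc != sb:
                        out.add(Triplet.of(sa, sb, sc))
    return out


def informative_triplets(gt: EventLabeledGeneTree) -> set[Triplet]:
    """R(T;t,sigma): union of speciation- and transfer-forced triplets."""
    return speciation_triplets(gt) | transfer_triplets(gt)
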