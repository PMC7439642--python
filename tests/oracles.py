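"""Independent brute-force oracles used to cross-check the implementation.

Everything here works from the definitions directly -- leaf-triple
enumeration, the classical BUILD recursion, a from-scratch rebuild of the
timing graph checked with networkx's own cycle test -- and deliberately
shares no code path with the library functions it validates.
"""

from __future__ import annotations

import networkx as nx

from gtcons.gene_tree import (
    DUPLICATION,
    LEAF,
    SPECIATION,
    TRANSFER,
    EventLabeledGeneTree,
)
from gtcons.simulate import enumerate_binary_species_trees
from gtcons.tree import RootedTree, Triplet


def brute_informative_triplets(gt: EventLabeledGeneTree) -> set[Triplet]:
    """Literal informative-triplet enumeration over ordered leaf triples.

    Clause 1: ab|c displayed inside one forest component with a
    speciation at the component-lca of {a,b,c}.  Clause 2: a,b below one
    endpoint and c below the other endpoint of a transfer edge.
    """
    tree = gt.tree
    leaves = tree.leaves()
    out: set[Triplet] = set()
    for a in leaves:
        for b in leaves:
            for c in leaves:
                if len({a, b, c}) != 3:
                    continue
                sa, sb, sc = gt.sigma[a], gt.sigma[b], gt.sigma[c]
                if len({sa, sb, sc}) != 3:
                    continue
                if not gt.same_component(a, b, c):
                    continue
                lab = tree.lca([a, b])
                labc = tree.lca([a, b, c])
                # within one component the tree order equals the forest order
                if lab != labc and gt.event[labc] == SPECIATION:
                    out.add(Triplet.of(sa, sb, sc))
    for (x, y) in gt.transfer_edges:
        for (pair_end, single_end) in ((x, y), (y, x)):
            pair_leaves = gt.forest_leaves(pair_end)
            single_leaves = gt.forest_leaves(single_end)
            for a in pair_leaves:
                for b in pair_leaves:
                    if a == b or gt.sigma[a] == gt.sigma[b]:
                        continue
                    for c in single_leaves:
                        if gt.sigma[c] in (gt.sigma[a], gt.sigma[b]):
                            continue
                        out.add(Triplet.of(gt.sigma[a], gt.sigma[b], gt.sigma[c]))
    return out


def aho_build_compatible(R: set[Triplet], labels: set[str]) -> bool:
    """Classical BUILD recursion: is the triplet set compatible?"""
    if len(labels) <= 2:
        return True
    G = nx.Graph()
    G.add_nodes_from(labels)
    for t in R:
        if t.a in labels and t.b in labels and t.c in labels:
            G.add_edge(t.a, t.b)
    comps = list(nx.connected_components(G))
    if len(comps) == 1:
        return False
    return all(aho_build_compatible(R, set(c)) for c in comps)


def literal_aux_graph(gt: EventLabeledGeneTree, S: RootedTree) -> nx.MultiDiGraph:
    """From-scratch A(T,S) built straight from the four edge rules."""
    def mu_hat(v: str) -> str:
        return S.lca(S.leaf_by_label(sp) for sp in gt.sigma_forest(v))

    G = nx.MultiDiGraph()
    for v in gt.tree.vertices:
        G.add_node(("T", v))
    for v in S.vertices:
        G.add_node(("S", v))
    subst = {
        v: (("S", mu_hat(v)) if gt.event[v] in (LEAF, SPECIATION) else ("T", v))
        for v in gt.tree.vertices
    }
    for (u, v) in gt.tree.edges():
        G.add_edge(subst[u], subst[v], cls="A1")
    for (x, y) in S.edges():
        G.add_edge(("S", x), ("S", y), cls="A2")
    for u in gt.tree.vertices:
        if gt.event[u] in (DUPLICATION, TRANSFER):
            G.add_edge(("T", u), ("S", mu_hat(u)), cls="A3")
    for (u, v) in gt.transfer_edges:
        G.add_edge(("S", S.lca([mu_hat(u), mu_hat(v)])), ("T", u), cls="A4")
    return G


def displays_via_restrict(S: RootedTree, t: Triplet) -> bool:
    """Does S display ab|c?  Checked on the restriction to {a, b, c}."""
    sub = S.restrict({t.a, t.b, t.c})
    kids = sub.children(sub.root)
    if len(kids) != 2:
        return False  # unresolved: displays none of the three triplets
    return any(sub.is_leaf(k) and sub.leaf_label[k] == t.c for k in kids)


def literal_time_consistent(gt: EventLabeledGeneTree, S: RootedTree) -> bool:
    """The two characterizing conditions, evaluated with independent machinery.

    Triplet display via restriction topologies and acyclicity via
    networkx's cycle detection on the literally rebuilt graph.
    """
    for t in brute_informative_triplets(gt):
        if not displays_via_restrict(S, t):
            return False
    G = literal_aux_graph(gt, S)
    # networkx treats a self-loop as a cycle, as required here
    return nx.is_directed_acyclic_graph(G)


def brute_gtc_verdict(gt: EventLabeledGeneTree) -> bool:
    """Sweep every binary species tree; True iff some tree passes both
    characterizing conditions."""
    return any(
        literal_time_consistent(gt, S)
        for S in enumerate_binary_species_trees(gt.species())
    )


def displayed_triplets_via_restrict(tree: RootedTree) -> set[Triplet]:
    """rt(T) recomputed by restricting to every leaf triple."""
    labels = sorted(tree.leaf_labels())
    out: set[Triplet] = set()
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            for k in range(j + 1, len(labels)):
                c = labels[k]
                sub = tree.restrict({a, b, c})
                root_kids = sub.children(sub.root)
                if len(root_kids) != 2:
                    continue  # star on three leaves: no triplet displayed
                for kid in root_kids:
                    if sub.is_leaf(kid):
                        outgroup = sub.leaf_label[kid]
                        pair = [x for x in (a, b, c) if x != outgroup]
                        out.add(Triplet.of(pair[0], pair[1], outgroup))
    return out


def is_good_split(
    gt: EventLabeledGeneTree,
    S: RootedTree,
    x: str,
    A: set[str],
    B: set[str],
) -> bool:
    """Literal re-check of the good-split conditions for a bipartition.

    The refined tree must agree with the informative triplets and every
    in-neighbor of the split cherry in the refreshed timing graph must
    already belong to the maximal topological sort of the old graph.
    """
    from gtcons.aux_graph import build_aux_graph, maximal_topological_sort
    from gtcons.refine import apply_split_refinement
    from gtcons.triplets import informative_triplets

    R = informative_triplets(gt)
    Q = maximal_topological_sort(build_aux_graph(gt, S))
    S2 = apply_split_refinement(S, x, A, B)
    if not S2.agrees(R):
        return False
    A2 = build_aux_graph(gt, S2)
    return all(n in Q.members for n in A2.in_neighbors(("S", x)) if n != ("S", x))
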