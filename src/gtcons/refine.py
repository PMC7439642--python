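"""Good split refinements of an almost binary species tree.

Refining a non-binary cherry x means partitioning its children into two
blocks and inserting a new parent above each block of size >= 2.  A split
is *good* when the refined tree still agrees with the informative triplets
and every in-neighbor of x in the refreshed timing graph already sits in
the maximal topological sort -- i.e. the refinement makes progress towards
an acyclic A(T,S).

Good splits are found through an undirected auxiliary graph on the
cherry's leaves (an extension of the classical BUILD/Aho graph): two
species are joined whenever separating them would either contradict an
informative triplet (C1) or create a timing edge into x from a vertex that
is not yet sortable (C2-C4).  Any bipartition across which no edge runs
yields a good split; if every such graph is connected, the instance has no
solution at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .aux_graph import TopoSort, build_aux_graph, maximal_topological_sort
from .gene_tree import DUPLICATION, SPECIATION, TRANSFER, EventLabeledGeneTree
from .tree import RootedTree, Triplet


@dataclass
class GoodSplitGraph:
    """The split-guidance graph at one cherry; edges carry condition tags."""

    cherry: str
    graph: nx.Graph

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes())

    def edge_conditions(self, a: str, b: str) -> set[str]:
        return self.graph.edges[a, b]["conds"]

    def to_dot(self) -> str:
        lines = ["graph good_split {"]
        for v in sorted(self.graph.nodes()):
            lines.append(f'  "{v}";')
        for a, b, data in self.graph.edges(data=True):
            label = ",".join(sorted(data["conds"]))
            lines.append(f'  "{a}" -- "{b}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def good_split_graph(
    gt: EventLabeledGeneTree,
    S: RootedTree,
    Q: TopoSort,
    x: str,
    R: Optional[set[Triplet]] = None,
    mu: Optional[dict[str, str]] = None,
) -> GoodSplitGraph:
    """Build the good-split-graph G((T;t,sigma), S, x) at cherry x.

    ``Q`` must be the maximal topological sort of A(T,S); ``R`` and ``mu``
    (the informative triplets and the LCA-map) are recomputed when not
    supplied.
    """
    kids = S.children(x)
    if not kids or not all(S.is_leaf(c) for c in kids):
        raise ValueError(f"{x!r} is not a cherry of the species tree")
    if R is None:
        from .triplets import informative_triplets

        R = informative_triplets(gt)
    if mu is None:
        from .aux_graph import lca_map

        mu = lca_map(gt, S)
    under_x = {S.leaf_label[c] for c in kids}
    G = nx.Graph()
    G.add_nodes_from(under_x)

    def add_edge(a: str, b: str, cond: str) -> None:
        if G.has_edge(a, b):
            G.edges[a, b]["conds"].add(cond)
        else:
            G.add_edge(a, b, conds={cond})

    # C1: separating a and b would contradict an informative triplet ab|c
    # whose outgroup also lives under x.
    for t in R:
        if t.a in under_x and t.b in under_x and t.c in under_x:
            add_edge(t.a, t.b, "C1")

    unsorted_dt = {
        u
        for u in gt.tree.vertices
        if gt.event.get(u) in (DUPLICATION, TRANSFER) and ("T", u) not in Q
    }

    def add_pairs(species: Iterable[str], cond: str) -> None:
        pool = sorted(set(species) & under_x)
        for i, sa in enumerate(pool):
            for sb in pool[i + 1 :]:
                add_edge(sa, sb, cond)

    for (u, v) in gt.tree.edges():
        # C2: an unsorted duplication/transfer vertex above a speciation
        # child would gain an A1-edge into x if the child's species split.
        if (
            u in unsorted_dt
            and not gt.tree.is_leaf(v)
            and gt.event[v] == SPECIATION
        ):
            add_pairs(gt.sigma_forest(v), "C2")
        # C3: a speciation mapping to x above another speciation would put
        # a self-loop on x if the child's species split.
        if (
            not gt.tree.is_leaf(u)
            and not gt.tree.is_leaf(v)
            and gt.event[u] == SPECIATION
            and gt.event[v] == SPECIATION
            and mu[u] == x
        ):
            add_pairs(gt.sigma_forest(v), "C3")

    # C4: an unsorted duplication/transfer vertex would gain an A3-edge
    # into x if its own species set split.
    for u in unsorted_dt:
        add_pairs(gt.sigma_forest(u), "C4")

    return GoodSplitGraph(x, G)


def disconnected_bipartition(
    G: GoodSplitGraph,
) -> Optional[tuple[set[str], set[str]]]:
    """A bipartition of the cherry's leaves with no crossing edge.

    Returns ``None`` for a connected graph.  Otherwise the first block is
    the connected component containing the lexicographically smallest
    species (for determinism) and the second block is everything else.
    """
    comps = list(nx.connected_components(G.graph))
    if len(comps) <= 1:
        return None
    smallest = min(G.graph.nodes())
    A = next(c for c in comps if smallest in c)
    B = set(G.graph.nodes()) - A
    return set(A), B


def apply_split_refinement(
    S: RootedTree, x: str, A: Iterable[str], B: Iterable[str]
) -> RootedTree:
    """Resolve cherry x by the bipartition (A, B) of its children.

    Applies the extensions (x, A) then (x, B); blocks of size one attach
    directly to x.  An almost binary tree stays almost binary and gains
    exactly one binary internal vertex (when x has >= 3 children).
    """
    A, B = set(A), set(B)
    kids = set(S.children(x))
    if not A or not B or A & B or A | B != kids:
        raise ValueError("(A, B) must partition the children of the cherry")
    if len(kids) == 2:
        return S.copy()
    out = S
    if len(A) >= 2:
        out = out.apply_extension(x, A)
    if len(B) >= 2 and len(B) < len(out.children(x)):
        out = out.apply_extension(x, B)
    return out


def find_good_split(
    gt: EventLabeledGeneTree,
    S: RootedTree,
    R: Optional[set[Triplet]] = None,
) -> Optional[tuple[str, set[str], set[str]]]:
    """Search the cherries of S for a good split refinement.

    Requires S to agree with the informative triplets (the caller checks
    this once up front).  Scans non-binary cherries in canonical order,
    skipping those with a strict ancestor outside the maximal topological
    sort, and returns the first cherry with a disconnected guidance graph
    together with its deterministic bipartition.  ``None`` means no good
    split refinement exists, hence the instance has no solution.
    """
    if R is None:
        from .triplets import informative_triplets

        R = informative_triplets(gt)
    A = build_aux_graph(gt, S)
    Q = maximal_topological_sort(A)
    for x in S.cherries():
        if len(S.children(x)) < 3:
            continue
        ok = True
        anc = S.parent.get(x)
        while anc is not None:
            if ("S", anc) not in Q:
                ok = False
                break
            anc = S.parent.get(anc)
        if not ok:
            continue
        G = good_split_graph(gt, S, Q, x, R=R, mu=A.mu)
        parts = disconnected_bipartition(G)
        if parts is not None:
            return x, parts[0], parts[1]
    return None
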