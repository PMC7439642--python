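"""The LCA-map and the auxiliary timing graph A(T,S).

A(T,S) is a directed graph on V(T) union V(S) whose edges encode "must
have existed no later than" constraints between gene-tree and species-tree
vertices.  Together with triplet display, its acyclicity characterizes the
existence of a time-consistent reconciliation:

* A1 -- each gene-tree edge, with speciation/leaf endpoints replaced by
  their LCA-map images in S (self-loops can arise and are kept);
* A2 -- the species-tree edges;
* A3 -- each duplication/transfer vertex points to its LCA-map image;
* A4 -- for each transfer edge (u,v), the species vertex
  lca_S(mu(u), mu(v)) points back to u: the donor lineage must predate the
  divergence that separated donor and recipient.

The graph is a pure function of (T;t,sigma) and S; no reconciliation map
is needed to build it.  Gene and species vertices are namespaced as
("T", v) and ("S", v) so the two vertex sets can never collide.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import networkx as nx

from .gene_tree import DUPLICATION, LEAF, SPECIATION, TRANSFER, EventLabeledGeneTree
from .tree import RootedTree

Node = tuple[str, str]  # ("T", vertex) or ("S", vertex)


def lca_map(gt: EventLabeledGeneTree, S: RootedTree) -> dict[str, str]:
    """mu_hat: every gene-tree vertex -> lca_S of its forest species set.

    Total and unique for any species tree covering the species image of
    sigma, whether or not any reconciliation exists.
    """
    missing = gt.species() - S.leaf_labels()
    if missing:
        raise ValueError(f"species missing from the species tree: {sorted(missing)}")
    out: dict[str, str] = {}
    for v in gt.tree.preorder():
        out[v] = S.lca(S.leaf_by_label(sp) for sp in gt.sigma_forest(v))
    return out


@dataclass
class AuxGraph:
    """A(T,S) as a class-tagged multidigraph plus its builders' inputs."""

    graph: nx.MultiDiGraph
    mu: dict[str, str]

    def edges_of_class(self, cls: str) -> list[tuple[Node, Node]]:
        return [
            (u, v)
            for u, v, data in self.graph.edges(data=True)
            if data["cls"] == cls
        ]

    def self_loops(self) -> set[Node]:
        return {u for u, v in self.graph.edges() if u == v}

    def in_neighbors(self, node: Node) -> set[Node]:
        return set(self.graph.predecessors(node))


def build_aux_graph(gt: EventLabeledGeneTree, S: RootedTree) -> AuxGraph:
    """Construct A(T,S) from scratch for the given pair."""
    mu = lca_map(gt, S)
    G = nx.MultiDiGraph()
    for v in gt.tree.vertices:
        G.add_node(("T", v))
    for v in S.vertices:
        G.add_node(("S", v))

    def image(v: str) -> Node:
        if gt.event[v] in (LEAF, SPECIATION):
            return ("S", mu[v])
        return ("T", v)

    for (u, v) in gt.tree.edges():
        G.add_edge(image(u), image(v), cls="A1")
    for (x, y) in S.edges():
        G.add_edge(("S", x), ("S", y), cls="A2")
    for u in gt.tree.preorder():
        if gt.event[u] in (DUPLICATION, TRANSFER):
            G.add_edge(("T", u), ("S", mu[u]), cls="A3")
    for (u, v) in gt.transfer_edges:
        top = S.lca([mu[u], mu[v]])
        G.add_edge(("S", top), ("T", u), cls="A4")
    return AuxGraph(G, mu)


@dataclass
class TopoSort:
    """A maximal partial topological sort Q and its vertex set M(Q)."""

    sequence: list[Node]
    members: frozenset[Node]

    def __contains__(self, node: Node) -> bool:
        return node in self.members


def _default_key(node: Node) -> tuple[int, str]:
    # species vertices first, then lexicographic id: fixes the sequence,
    # not the (order-invariant) member set
    return (0 if node[0] == "S" else 1, node[1])


def maximal_topological_sort(
    A: AuxGraph | nx.MultiDiGraph,
    key: Optional[Callable[[Node], object]] = None,
) -> TopoSort:
    """Kahn-style peeling of in-degree-0 vertices.

    Vertices carrying self-loops never enter the sort.  The member set
    M(Q) is independent of the tie-breaking order; ``key`` only fixes the
    emitted sequence.
    """
    G = A.graph if isinstance(A, AuxGraph) else A
    key = key or _default_key
    indeg: dict[Node, int] = {v: 0 for v in G.nodes()}
    for u, v in G.edges():
        indeg[v] += 1  # self-loops contribute, keeping their vertex stuck
    ready = [(key(v), v) for v, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    seq: list[Node] = []
    while ready:
        _, v = heapq.heappop(ready)
        seq.append(v)
        for _, w in G.out_edges(v):
            if w == v:
                continue
            indeg[w] -= 1
            if indeg[w] == 0:
                heapq.heappush(ready, (key(w), w))
    return TopoSort(seq, frozenset(seq))


def is_acyclic(A: AuxGraph | nx.MultiDiGraph) -> bool:
    """True iff the maximal topological sort exhausts every vertex."""
    G = A.graph if isinstance(A, AuxGraph) else A
    return len(maximal_topological_sort(A).members) == G.number_of_nodes()


def leaf_selfloop_screen(gt: EventLabeledGeneTree, S: RootedTree) -> bool:
    """True iff no leaf of S carries a self-loop in A(T,S).

    A self-loop on a species leaf survives every refinement of S, so a
    failing screen means the instance can be discarded immediately.
    """
    A = build_aux_graph(gt, S)
    leaves = {("S", v) for v in S.leaves()}
    return not (A.self_loops() & leaves)
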