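"""Reconciliation maps and time assignments.

Once a species tree passes verification, the gene tree is embedded into it
by the canonical LCA-based reconciliation: leaves and speciations map to
species vertices, duplications and transfers map to the species-tree edge
entering the lowest common ancestor of their transfer-free species set
(the conceptual planted edge above the root when that ancestor is the root
itself).  Species edges are written ``(parent, child)``; the planted edge
is ``(None, root)``.

Time maps make the embedding explicit: every vertex receives a time,
strictly increasing from root to leaves in both trees, equal across the
map for speciations and leaves (B1), and strictly inside the host edge's
interval for duplications and transfers (B2).  Times are integer ranks of
a strict-precedence digraph, so all checks are exact.

Both constructions have independent checkers that re-validate every
constraint literally; the checkers treat violations as data, so crafted
negative instances can be probed without exceptions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Union

import networkx as nx

from .aux_graph import build_aux_graph, is_acyclic, lca_map
from .gene_tree import DUPLICATION, LEAF, SPECIATION, TRANSFER, EventLabeledGeneTree
from .tree import RootedTree

SpeciesEdge = tuple[Optional[str], str]  # (parent or None for planted, child)
Image = Union[str, SpeciesEdge]


@dataclass
class ReconciliationMap:
    """mu: gene vertices -> species vertices (leaves/speciations) or edges."""

    mapping: dict[str, Image]

    def __getitem__(self, v: str) -> Image:
        return self.mapping[v]


@dataclass
class TimeAssignment:
    """Integer-valued time maps for the gene tree and the species tree."""

    tau_T: dict[str, int]
    tau_S: dict[str, int]


def _is_edge_image(img: Image) -> bool:
    return isinstance(img, tuple)


def _images_comparable(S: RootedTree, a: Image, b: Image) -> bool:
    """Extended comparability on V(S) union E(S) (planted edge included).

    A vertex x lies below an edge (u,v) when x <= v; an edge (u,v) lies
    below a vertex y when u <= y; edges compare through their lower
    endpoints.  Two images are comparable when either lies below the
    other.
    """
    return _extended_leq(S, a, b) or _extended_leq(S, b, a) or a == b


def _embed(
    gt: EventLabeledGeneTree, S: RootedTree
) -> tuple[ReconciliationMap, TimeAssignment]:
    """Jointly construct the reconciliation map and exact integer times.

    The precedence digraph has one node per species vertex and per
    edge-mapped (duplication/transfer) gene vertex; speciations and
    leaves are collapsed onto their LCA-map images.  Its arcs are the
    species edges, a strict-order arc per gene-tree edge, an upper bound
    u -> mu_hat(u) per edge-mapped vertex, and a fork-separation lower
    bound z -> u (z the lca where two lineage images diverge) wherever
    incomparability of images is required: between the children of a
    speciation and across each transfer edge.
    Any valid time assignment linearizes this digraph, so under the
    verification precondition it is acyclic; integer ranks of a
    topological order are the times, with sinks peeled gene-first so each
    edge-mapped vertex lands on the lowest admissible species edge (the
    canonical edge entering its LCA-map image whenever feasible).
    """
    from .solve import verify_solution

    if not verify_solution(gt, S):
        raise ValueError(
            "pair fails verification (triplet display + acyclic A(T,S)); "
            "no time-consistent reconciliation exists"
        )
    mu_hat = lca_map(gt, S)
    dt = (DUPLICATION, TRANSFER)

    def point(v: str):
        if gt.event[v] in (LEAF, SPECIATION):
            return ("S", mu_hat[v])
        return ("T", v)

    H = nx.DiGraph()
    for x in S.vertices:
        H.add_node(("S", x))
    for (x, y) in S.edges():
        H.add_edge(("S", x), ("S", y))
    for v in gt.tree.preorder():
        if gt.event[v] in dt:
            H.add_edge(("T", v), ("S", mu_hat[v]))
    for (u, v) in gt.tree.edges():
        H.add_edge(point(u), point(v))

    def fork_bounds(u: str, other_image: str) -> None:
        # u must postdate the divergence z separating its image from the
        # other lineage's image; together with the walk-up edge selection
        # this keeps u's image strictly on its own side of z, hence
        # incomparable with anything on the other side
        z = S.lca([mu_hat[u], other_image])
        if z == mu_hat[u] or z == other_image:
            return  # comparable images: nothing to separate (checker flags)
        H.add_edge(("S", z), ("T", u))

    for p in gt.tree.preorder():
        if gt.tree.is_leaf(p) or gt.event[p] != SPECIATION:
            continue
        kids = gt.tree.children(p)
        for ci in kids:
            if gt.event[ci] not in dt:
                continue
            for cj in kids:
                if cj != ci:
                    fork_bounds(ci, mu_hat[cj])
    for (x, y) in gt.transfer_edges:
        fork_bounds(x, mu_hat[y])
        if gt.event[y] in dt:
            fork_bounds(y, mu_hat[x])

    # reverse Kahn peeling of sinks, gene vertices first: assigns the
    # largest free rank to a gene vertex whenever possible, pushing each
    # one onto the lowest species edge its constraints admit
    outdeg = {n: H.out_degree(n) for n in H.nodes()}
    ready = [
        ((0 if n[0] == "T" else 1, n[1]), n) for n, d in outdeg.items() if d == 0
    ]
    heapq.heapify(ready)
    rank: dict[tuple[str, str], int] = {}
    next_rank = H.number_of_nodes() - 1
    while ready:
        _, n = heapq.heappop(ready)
        rank[n] = next_rank
        next_rank -= 1
        for p, _ in H.in_edges(n):
            outdeg[p] -= 1
            if outdeg[p] == 0:
                heapq.heappush(ready, (((0 if p[0] == "T" else 1), p[1]), p))
    if len(rank) != H.number_of_nodes():  # pragma: no cover - contract
        raise RuntimeError(
            "internal error: precedence digraph cyclic despite verification"
        )

    tau_S = {x: rank[("S", x)] for x in S.vertices}
    mapping: dict[str, Image] = {}
    tau_T: dict[str, int] = {}
    for v in gt.tree.preorder():
        if gt.event[v] in (LEAF, SPECIATION):
            mapping[v] = mu_hat[v]
            tau_T[v] = tau_S[mu_hat[v]]
            continue
        r = rank[("T", v)]
        tau_T[v] = r
        below = mu_hat[v]
        anc = S.parent.get(below)
        while anc is not None and tau_S[anc] > r:
            below = anc
            anc = S.parent.get(below)
        # now anc is None (planted edge) or tau_S[anc] < r < tau_S[below]
        mapping[v] = (anc, below)
    return ReconciliationMap(mapping), TimeAssignment(tau_T, tau_S)


def construct_reconciliation(gt: EventLabeledGeneTree, S: RootedTree) -> ReconciliationMap:
    """A reconciliation map from (T;t,sigma) to S.

    Leaves and speciations go to their LCA-map image (forced by M1 and
    M2.i).  When the pair passes full verification, each
    duplication/transfer vertex goes to the species edge, on the path
    from its LCA-map image up to the planted edge, whose time interval
    contains the vertex's time in the joint embedding -- the edge
    entering the image itself whenever that choice is feasible -- and the
    map is time-consistent.  When S merely displays the informative
    triplets (so a reconciliation exists but no time-consistent one),
    the canonical entering-edge map is returned instead.
    """
    from .triplets import informative_triplets

    if is_acyclic(build_aux_graph(gt, S)):
        return _embed(gt, S)[0]
    for t in informative_triplets(gt):
        if not S.displays(t):
            raise ValueError(
                "species tree does not display the informative triplets; "
                "no reconciliation exists"
            )
    mu_hat = lca_map(gt, S)
    mapping: dict[str, Image] = {}
    for v in gt.tree.preorder():
        if gt.event[v] in (LEAF, SPECIATION):
            mapping[v] = mu_hat[v]
        else:
            y = mu_hat[v]
            mapping[v] = (S.parent.get(y), y)
    return ReconciliationMap(mapping)


def check_reconciliation(
    gt: EventLabeledGeneTree, S: RootedTree, mu: ReconciliationMap
) -> list[str]:
    """Literal re-validation of the reconciliation constraints M1-M3."""
    violations: list[str] = []
    tree = gt.tree
    m = mu.mapping

    for v in tree.preorder():
        img = m.get(v)
        if img is None:
            violations.append(f"M1: vertex {v} has no image")
            continue
        ev = gt.event[v]
        if ev == LEAF:
            if img != S.leaf_by_label(gt.sigma[v]):
                violations.append(f"M1: leaf {v} maps to {img}, not sigma({v})")
        elif ev == SPECIATION:
            want = S.lca(S.leaf_by_label(sp) for sp in gt.sigma_forest(v))
            if img != want:
                violations.append(f"M2.i: speciation {v} maps to {img}, not {want}")
            kids = tree.children(v)
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    if _images_comparable(S, m[kids[i]], m[kids[j]]):
                        violations.append(
                            f"M2.iv: children {kids[i]},{kids[j]} of speciation "
                            f"{v} have comparable images"
                        )
        else:
            if not _is_edge_image(img):
                violations.append(f"M2.ii: {ev} vertex {v} maps to a vertex")
            elif img[0] is not None and S.parent.get(img[1]) != img[0]:
                violations.append(f"M2.ii: image {img} of {v} is not an edge of S")

    for (x, y) in sorted(gt.transfer_edges):
        if x in m and y in m and _images_comparable(S, m[x], m[y]):
            violations.append(
                f"M2.iii: transfer edge ({x},{y}) has comparable images"
            )

    # M3 over all strict forest-ancestor pairs (paths without transfer edges)
    dt = (DUPLICATION, TRANSFER)
    for y in tree.preorder():
        stack = [
            c for c in tree.children(y) if (y, c) not in gt.transfer_edges
        ]
        while stack:
            x = stack.pop()
            if gt.event[x] in dt and gt.event[y] in dt:
                ok = _extended_leq(S, m[x], m[y])
                rel = "<="
            else:
                ok = _extended_leq(S, m[x], m[y]) and m[x] != m[y]
                rel = "<"
            if not ok:
                violations.append(
                    f"M3: mu({x}) {rel} mu({y}) fails along a transfer-free path"
                )
            stack.extend(
                c for c in tree.children(x) if (x, c) not in gt.transfer_edges
            )
    return violations


def _extended_leq(S: RootedTree, a: Image, b: Image) -> bool:
    """a <=_S b on the union of vertices and edges (planted edge included)."""
    if _is_edge_image(a):
        lo_a = a[1]
    else:
        lo_a = a
    if _is_edge_image(b):
        # a <= e=(u,v) iff a's lower end <= v
        return S.is_ancestor(b[1], lo_a)
    # b is a vertex: edge a=(u,v) <= y iff u >= ... e <= x iff u <= x:
    # the edge lies below vertex b iff its upper endpoint is a descendant
    # of b (planted edge lies below nothing).
    if _is_edge_image(a):
        if a[0] is None:
            return False
        return S.is_ancestor(b, a[0])
    return S.is_ancestor(b, lo_a)


def construct_time_assignment(
    gt: EventLabeledGeneTree, S: RootedTree, mu: ReconciliationMap
) -> TimeAssignment:
    """Exact integer time maps witnessing time-consistency of ``mu``.

    ``mu`` must be the map returned by :func:`construct_reconciliation`
    for the same pair: the embedding and its times are constructed
    jointly, so a foreign map is rejected as a usage error.  Under the
    verification precondition a valid assignment always exists; a checker
    failure afterwards would be an internal error.
    """
    mu2, tau = _embed(gt, S)
    if mu2.mapping != mu.mapping:
        raise ValueError(
            "mu does not match the joint embedding for this pair; use the "
            "map returned by construct_reconciliation"
        )
    return tau


def check_time_assignment(
    gt: EventLabeledGeneTree,
    S: RootedTree,
    mu: ReconciliationMap,
    tau: TimeAssignment,
) -> list[str]:
    """Literal re-validation of time-map strictness and the B1/B2 couplings."""
    violations: list[str] = []
    for (x, y) in S.edges():
        if not tau.tau_S[y] > tau.tau_S[x]:
            violations.append(f"order(S): tau_S({y}) <= tau_S({x})")
    # strictness on the gene tree uses *all* edges, transfer edges included
    for (u, v) in gt.tree.edges():
        if not tau.tau_T[v] > tau.tau_T[u]:
            violations.append(f"order(T): tau_T({v}) <= tau_T({u})")
    for v in gt.tree.preorder():
        img = mu.mapping[v]
        if gt.event[v] in (LEAF, SPECIATION):
            if tau.tau_T[v] != tau.tau_S[img]:
                violations.append(f"B1: tau_T({v}) != tau_S(mu({v}))")
        else:
            x, y = img
            if not tau.tau_T[v] < tau.tau_S[y]:
                violations.append(f"B2: tau_T({v}) >= tau_S({y})")
            if x is not None and not tau.tau_T[v] > tau.tau_S[x]:
                violations.append(f"B2: tau_T({v}) <= tau_S({x})")
    return violations
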