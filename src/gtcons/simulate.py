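"""Synthetic instances: DTL simulation, worked-example fixture, enumerators.

The simulator grows a gene tree inside a known timed binary species tree
under a duplication-transfer-loss model: events arrive at exponential
waiting times along each gene lineage, transfers jump to a species branch
alive at the transfer time (so a genuine time-consistent history exists by
construction), and losses prune lineages.  The observable gene tree is
what remains after removing lost subtrees, suppressing single-child
vertices, and discarding transferred copies whose donor-side lineage left
no surviving trace -- the post-processing that restores the observability
axioms O1-O3.  Every returned instance is therefore solvable, with the
(restriction of the) true species tree as a witness.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator, Optional

from .gene_tree import (
    DUPLICATION,
    SPECIATION,
    TRANSFER,
    EventLabeledGeneTree,
)
from .tree import RootedTree, read_newick


@dataclass
class SimulationParams:
    """Knobs of the duplication-transfer-loss simulator.

    Rates are per gene lineage per unit time; the species tree has total
    height 1, so a rate of 0.3 means on average 0.3 events of that kind on
    a root-to-leaf path.
    """

    n_species: int = 8
    duplication_rate: float = 0.3
    transfer_rate: float = 0.3
    loss_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if min(self.duplication_rate, self.transfer_rate, self.loss_rate) < 0:
            raise ValueError("rates must be non-negative")


class _Resample(Exception):
    """Internal: the draw left no observable gene (or exploded); retry."""


def _species_labels(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("A") + i) for i in range(n)]
    return [f"S{i:03d}" for i in range(n)]


def _random_timed_species_tree(
    n: int, rng: random.Random
) -> tuple[RootedTree, dict[str, float]]:
    """A random binary species tree with strictly ordered internal times.

    Leaves sit at time 1.0; the n-1 internal vertices get distinct times
    in (0,1) by successive random joins (a Kingman-style topology).
    """
    labels = _species_labels(n)
    times: dict[str, float] = {lab: 1.0 for lab in labels}
    if n == 1:
        return RootedTree(labels[0], {}, {labels[0]: labels[0]}), times
    merge_times = sorted((rng.uniform(0.0, 1.0) for _ in range(n - 1)), reverse=True)
    children: dict[str, list[str]] = {}
    lineages = list(labels)
    counter = 0
    for t in merge_times:
        i = rng.randrange(len(lineages))
        j = rng.randrange(len(lineages) - 1)
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        vid = f"v{counter}"
        counter += 1
        children[vid] = [a, b]
        times[vid] = t
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(vid)
    root = lineages[0]
    return RootedTree(root, children, {lab: lab for lab in labels}), times


class _HistNode:
    """One vertex of the full (unpruned) simulated gene history."""

    __slots__ = ("kind", "children", "transfer_child", "species", "lost")

    def __init__(self, kind: str, species: Optional[str] = None):
        self.kind = kind  # "leaf" | "S" | "D" | "T" | "loss"
        self.children: list["_HistNode"] = []
        self.transfer_child: Optional["_HistNode"] = None
        self.species = species
        self.lost = False


def _grow(
    S: RootedTree,
    times: dict[str, float],
    params: SimulationParams,
    rng: random.Random,
    budget: list[int],
) -> _HistNode:
    """Grow one gene history starting at the species root."""

    def run_branch(parent: str, child: str, t: float) -> _HistNode:
        # a gene lineage inside species branch (parent, child), at time t
        total = params.duplication_rate + params.transfer_rate + params.loss_rate
        while True:
            budget[0] -= 1
            if budget[0] <= 0:
                raise _Resample
            dt = rng.expovariate(total) if total > 0 else float("inf")
            t_end = times[child]
            if t + dt >= t_end:
                return at_vertex(child)
            t = t + dt
            u = rng.uniform(0.0, total)
            if u < params.loss_rate:
                node = _HistNode("loss")
                node.lost = True
                return node
            if u < params.loss_rate + params.duplication_rate:
                node = _HistNode(DUPLICATION)
                node.children = [
                    run_branch(parent, child, t),
                    run_branch(parent, child, t),
                ]
                return node
            # transfer: pick a recipient branch alive at time t
            alive = [
                (p, c)
                for (p, c) in S.edges()
                if times[p] < t < times[c] and (p, c) != (parent, child)
            ]
            if not alive:
                continue  # no coexisting lineage; the event has no effect
            rp, rc = alive[rng.randrange(len(alive))]
            node = _HistNode(TRANSFER)
            vertical = run_branch(parent, child, t)
            transferred = run_branch(rp, rc, t)
            node.children = [vertical, transferred]
            node.transfer_child = transferred
            return node

    def at_vertex(v: str) -> _HistNode:
        if S.is_leaf(v):
            return _HistNode("leaf", species=S.leaf_label[v])
        node = _HistNode(SPECIATION)
        node.children = [run_branch(v, c, times[v]) for c in S.children(v)]
        return node

    return at_vertex(S.root)


def _prune(node: _HistNode) -> Optional[_HistNode]:
    """Observable part of a history subtree, or None if nothing survives.

    Lost subtrees disappear; single-survivor speciations and duplications
    are suppressed; a transfer vertex keeps its label only when both sides
    survive, loses the transferred copy when the donor side is extinct
    (no historical trace of the transfer would remain), and is suppressed
    to its vertical child when the transferred copy is extinct.
    """
    if node.kind == "loss":
        return None
    if node.kind == "leaf":
        return node
    if node.kind == TRANSFER:
        vertical = next(c for c in node.children if c is not node.transfer_child)
        obs_vert = _prune(vertical)
        if obs_vert is None:
            return None
        obs_trans = _prune(node.transfer_child)
        if obs_trans is None:
            return obs_vert
        out = _HistNode(TRANSFER)
        out.children = [obs_vert, obs_trans]
        out.transfer_child = obs_trans
        return out
    survivors = [s for s in map(_prune, node.children) if s is not None]
    if not survivors:
        return None
    if len(survivors) == 1:
        return survivors[0]
    out = _HistNode(node.kind)
    out.children = survivors
    return out


def _to_gene_tree(root: _HistNode) -> EventLabeledGeneTree:
    children: dict[str, list[str]] = {}
    leaf_label: dict[str, str] = {}
    event: dict[str, str] = {}
    sigma: dict[str, str] = {}
    transfer_edges: set[tuple[str, str]] = set()
    counter = 0
    per_species: dict[str, int] = {}

    def visit(node: _HistNode) -> str:
        nonlocal counter
        if node.kind == "leaf":
            sp = node.species
            per_species[sp] = per_species.get(sp, 0) + 1
            vid = f"{sp}_{per_species[sp]}"
            leaf_label[vid] = vid
            sigma[vid] = sp
            return vid
        vid = f"g{counter}"
        counter += 1
        event[vid] = node.kind
        kids = [visit(c) for c in node.children]
        children[vid] = kids
        if node.kind == TRANSFER and node.transfer_child is not None:
            idx = node.children.index(node.transfer_child)
            transfer_edges.add((vid, kids[idx]))
        return vid

    root_id = visit(root)
    tree = RootedTree(root_id, children, leaf_label)
    return EventLabeledGeneTree(tree, event, transfer_edges, sigma)


def simulate_instance(
    params: SimulationParams,
) -> tuple[EventLabeledGeneTree, RootedTree]:
    """Draw one solvable instance: (gene tree, witness species tree).

    The returned species tree is the true simulated tree restricted to the
    species with at least one surviving gene, so the pair always passes
    verification.  A draw in which every gene is lost (or that exceeds a
    generous event budget) is resampled from the same stream, with a
    bounded number of retries.
    """
    rng = random.Random(params.seed)
    for _ in range(100):
        S, times = _random_timed_species_tree(params.n_species, rng)
        budget = [200 * params.n_species + 500]
        try:
            history = _grow(S, times, params, rng, budget)
        except _Resample:
            continue
        observable = _prune(history)
        if observable is None or observable.kind == "leaf":
            continue  # total or near-total extinction; redraw
        gt = _to_gene_tree(observable)
        witness = S.restrict(gt.species()) if gt.species() != S.leaf_labels() else S
        return gt, witness
    raise RuntimeError("simulation failed to produce an observable gene tree")


# -- worked example ---------------------------------------------------------

#: The running worked example in NHX form: a binary gene tree over
#: species A-D whose informative triplets are {AB|D, AC|D}, for which the
#: least-resolved displaying tree ((A,B,C),D) admits no time-consistent
#: reconciliation but its refinement (((A,B),C),D) does.  Every property
#: stated here is asserted by the test suite.
_V = "(a1[&&NHX:S=A],b2[&&NHX:S=B])[&&NHX:ev=S]"  # speciation over A, B
_G = f"({_V},a2[&&NHX:S=A])[&&NHX:ev=D:xfer=1]"  # duplication, received by transfer
_W = f"(d1[&&NHX:S=D],{_G})[&&NHX:ev=T:xfer=1]"  # D-lineage donor, itself transferred
_U3 = f"(c1[&&NHX:S=C],{_W})[&&NHX:ev=T]"
_U2 = f"({_U3},b1[&&NHX:S=B:xfer=1])[&&NHX:ev=T]"
_S4 = "(a3[&&NHX:S=A],c2[&&NHX:S=C])[&&NHX:ev=S]"
_U4 = f"({_S4},d2[&&NHX:S=D:xfer=1])[&&NHX:ev=T]"
FIG1_NHX = f"({_U2},{_U4})[&&NHX:ev=D];"


def fig1_fixture() -> tuple[EventLabeledGeneTree, RootedTree, RootedTree]:
    """The worked example: gene tree, least-resolved tree, binary tree.

    Returns ``(gt, S_lr, S_bin)`` where S_lr = ((A,B,C),D) displays the
    informative triplets but admits no time-consistent reconciliation,
    while the binary refinement S_bin = (((A,B),C),D) admits one.
    """
    from .gene_tree import read_labeled_gene_tree

    gt = read_labeled_gene_tree(FIG1_NHX)
    least_resolved = read_newick("((A,B,C),D);")
    middle = read_newick("(((A,B),C),D);")
    return gt, least_resolved, middle


# -- crafted instances ------------------------------------------------------


def conflicting_caterpillars(
    species: "list[str] | tuple[str, ...]", seed: int
) -> EventLabeledGeneTree:
    """Two speciation caterpillars with shuffled species orders under a
    duplication root.

    The informative triplets are the union of the two caterpillars'
    triplet sets, which for most permutations is incompatible -- a source
    of valid but unsolvable instances (the verdict is still decided by the
    solver or an oracle, never assumed).
    """
    rng = random.Random(seed)
    species = list(species)
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    perm1, perm2 = list(species), list(species)
    rng.shuffle(perm1)
    rng.shuffle(perm2)
    children: dict[str, list[str]] = {}
    leaf_label: dict[str, str] = {}
    event: dict[str, str] = {}
    sigma: dict[str, str] = {}
    counter = [0]

    def caterpillar(perm: list[str], tag: str) -> str:
        ids = []
        for sp in perm:
            lid = f"{sp}_{tag}"
            leaf_label[lid] = lid
            sigma[lid] = sp
            ids.append(lid)
        node = ids[0]
        for nxt in ids[1:]:
            vid = f"g{counter[0]}"
            counter[0] += 1
            children[vid] = [node, nxt]
            event[vid] = SPECIATION
            node = vid
        return node

    r1 = caterpillar(perm1, "x")
    r2 = caterpillar(perm2, "y")
    children["root"] = [r1, r2]
    event["root"] = DUPLICATION
    tree = RootedTree("root", children, leaf_label)
    return EventLabeledGeneTree(tree, event, set(), sigma)


def relabel_perturbation(
    gt: EventLabeledGeneTree, seed: int, prob: float = 0.35
) -> Optional[EventLabeledGeneTree]:
    """Randomly reassign leaf species; None if observability breaks.

    Perturbed instances need not be solvable, which makes them useful
    negatives-by-chance for oracle comparisons.
    """
    rng = random.Random(seed)
    species = sorted(gt.species())
    sigma = dict(gt.sigma)
    for v in gt.tree.leaves():
        if rng.random() < prob:
            sigma[v] = rng.choice(species)
    gt2 = EventLabeledGeneTree(
        gt.tree, dict(gt.event), set(gt.transfer_edges), sigma
    )
    if gt2.validate_observability():
        return None
    return gt2


# -- exhaustive species-tree enumeration (oracle support) -------------------


def enumerate_binary_species_trees(species: set[str]) -> Iterator[RootedTree]:
    """Yield every rooted binary tree on the given labels exactly once.

    There are (2n-3)!! such trees; the enumeration is guarded to n <= 7
    leaves.  Trees are produced in a deterministic order by inserting
    labels (sorted) one at a time into every edge and above the root.
    """
    labels = sorted(species)
    n = len(labels)
    if not 1 <= n <= 7:
        raise ValueError("enumeration supports 1..7 species")

    def insert(shape, leaf):
        # yield all shapes obtained by attaching `leaf` into `shape`
        yield (shape, leaf)  # new root above everything
        if isinstance(shape, tuple):
            left, right = shape
            for new_left in insert(left, leaf):
                yield (new_left, right)
            for new_right in insert(right, leaf):
                yield (left, new_right)

    def shapes(k):
        if k == 1:
            yield labels[0]
            return
        for shape in shapes(k - 1):
            yield from insert(shape, labels[k - 1])

    def to_newick(shape) -> str:
        if isinstance(shape, str):
            return shape
        return "(" + to_newick(shape[0]) + "," + to_newick(shape[1]) + ")"

    for shape in shapes(n):
        yield read_newick(to_newick(shape) + ";")
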