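"""Deciding and constructing time-consistent species trees (the GTC problem).

Given an event-labeled gene tree and an almost binary species tree
(default: the star tree over the observed species), the solver looks for a
binary refinement that displays every informative triplet and whose timing
graph A(T,S) is acyclic -- exactly the trees admitting a time-consistent
reconciliation.  The search applies good split refinements until the tree
is binary or no good split exists; the latter certifies that no solution
exists at all.  Each iteration adds one binary internal vertex, so the
loop runs at most |species| - 2 times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .aux_graph import build_aux_graph, is_acyclic
from .gene_tree import EventLabeledGeneTree
from .refine import apply_split_refinement, find_good_split
from .tree import RootedTree, star_tree
from .triplets import informative_triplets

SOLVED = "solved"
NO_SOLUTION = "no_solution"


class InvalidInstance(ValueError):
    """Raised when an instance violates the solver's preconditions."""


@dataclass
class GtcInstance:
    """A gene tree plus an almost binary species tree to be refined."""

    gene_tree: EventLabeledGeneTree
    species_tree: Optional[RootedTree] = None

    def __post_init__(self) -> None:
        if self.species_tree is None:
            self.species_tree = star_tree(self.gene_tree.species())
        if not self.species_tree.is_almost_binary():
            raise InvalidInstance("species tree is not almost binary")
        if self.species_tree.leaf_labels() != self.gene_tree.species():
            raise InvalidInstance(
                "species tree leaves must equal the species image of sigma"
            )


@dataclass
class GtcResult:
    """Outcome of a solver run, including the refinement trace."""

    status: str
    species_tree: Optional[RootedTree] = None
    reason: str = ""
    trace: list[tuple[str, frozenset[str], frozenset[str]]] = field(
        default_factory=list
    )

    @property
    def solved(self) -> bool:
        return self.status == SOLVED


def verify_solution(gt: EventLabeledGeneTree, S: RootedTree) -> bool:
    """True iff S displays every informative triplet and A(T,S) is acyclic.

    These two conditions characterize the species trees admitting a
    time-consistent reconciliation with the gene tree.
    """
    if not (gt.species() <= S.leaf_labels()):
        raise ValueError("species tree does not cover the species image")
    for t in informative_triplets(gt):
        if not S.displays(t):
            return False
    return is_acyclic(build_aux_graph(gt, S))


def solve(inst: GtcInstance) -> GtcResult:
    """Run the refinement loop on a GTC instance.

    Pre-checks reject invalid gene trees outright; a species-leaf
    self-loop in A(T,S) or disagreement of S with the informative triplets
    means no refinement can succeed.  While S is non-binary, a good split
    refinement is applied; if none exists the instance has no solution.
    On a binary S the two characterizing conditions are checked directly.
    """
    gt = inst.gene_tree
    violations = gt.validate_observability()
    if violations:
        raise InvalidInstance(
            "gene tree violates observability axioms: " + "; ".join(violations)
        )
    S = inst.species_tree
    R = informative_triplets(gt)

    from .aux_graph import leaf_selfloop_screen

    if not leaf_selfloop_screen(gt, S):
        return GtcResult(NO_SOLUTION, reason="species-leaf self-loop in A(T,S)")
    if not S.agrees(R):
        bad = next(
            t
            for t in sorted(R)
            if not S.agrees([t])
        )
        return GtcResult(
            NO_SOLUTION,
            reason=f"species tree contradicts informative triplet {bad}",
        )

    trace: list[tuple[str, frozenset[str], frozenset[str]]] = []
    max_iter = max(len(gt.species()) - 2, 0)
    for _ in range(max_iter + 1):
        if S.is_binary():
            break
        found = find_good_split(gt, S, R=R)
        if found is None:
            return GtcResult(
                NO_SOLUTION,
                reason="no good split refinement exists",
                trace=trace,
            )
        x, A, B = found
        trace.append((x, frozenset(A), frozenset(B)))
        S = apply_split_refinement(S, x, A, B)
    else:  # pragma: no cover - the loop bound is a hard invariant
        raise AssertionError("refinement loop exceeded |species| - 2 iterations")

    if verify_solution(gt, S):
        return GtcResult(SOLVED, species_tree=S, trace=trace)
    return GtcResult(
        NO_SOLUTION,
        reason="binary refinement fails triplet display or acyclicity",
        trace=trace,
    )
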