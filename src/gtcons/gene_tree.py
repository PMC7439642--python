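"""Event-labeled gene trees (T; t, sigma).

A gene tree carries an event label on every vertex -- leaf, speciation
(``S``), duplication (``D``) or transfer origin (``T``) -- a set of transfer
edges (each starting at a transfer vertex), and a gene-to-species map
``sigma`` on its leaves.  Removing the transfer edges yields the
transfer-free forest; the species sets sigma_forest(v) of vertices within
their forest component drive everything else in the package.

File format: NHX-annotated Newick.  Internal vertices carry
``[&&NHX:ev=S|D|T]``; a transfer edge is flagged on its child end with
``xfer=1``; leaf species are given as ``S=<name>`` tags or via a separate
two-column mapping.

Parsing and validation of the observability axioms (O1-O3) are separate
steps, so syntactically well-formed but biologically invalid instances can
be loaded and reported on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy

from .tree import ParseError, RootedTree, _from_dendropy

LEAF = "leaf"
SPECIATION = "S"
DUPLICATION = "D"
TRANSFER = "T"

_INTERNAL_EVENTS = {SPECIATION, DUPLICATION, TRANSFER}


class FormatError(ValueError):
    """Raised when an annotated gene-tree file violates the dialect."""


@dataclass
class EventLabeledGeneTree:
    """A gene tree with vertex events, transfer edges and species map."""

    tree: RootedTree
    event: dict[str, str]
    transfer_edges: set[tuple[str, str]]
    sigma: dict[str, str]

    def __post_init__(self) -> None:
        for v in self.tree.vertices:
            ev = self.event.get(v)
            if self.tree.is_leaf(v):
                if ev not in (None, LEAF):
                    raise FormatError(f"leaf {v!r} carries internal event {ev!r}")
                self.event[v] = LEAF
                if v not in self.sigma:
                    raise FormatError(f"leaf {v!r} has no species assignment")
            else:
                if ev not in _INTERNAL_EVENTS:
                    raise FormatError(f"internal vertex {v!r} lacks an event label")
        for (x, y) in self.transfer_edges:
            if self.tree.parent.get(y) != x:
                raise FormatError(f"transfer edge ({x},{y}) is not an edge of the tree")
            if self.event[x] != TRANSFER:
                raise FormatError(
                    f"transfer edge ({x},{y}) starts at a non-transfer vertex"
                )
        self._comp_root_cache: Optional[dict[str, str]] = None
        self._sigma_forest_cache: Optional[dict[str, frozenset[str]]] = None

    # -- species -----------------------------------------------------------

    def species(self) -> set[str]:
        return set(self.sigma.values())

    # -- transfer-free forest ---------------------------------------------

    def component_root(self, v: str) -> str:
        """Root of v's connected component in the transfer-free forest."""
        if self._comp_root_cache is None:
            cache: dict[str, str] = {}
            for u in self.tree.preorder():
                p = self.tree.parent.get(u)
                if p is None or (p, u) in self.transfer_edges:
                    cache[u] = u
                else:
                    cache[u] = cache[p]
            self._comp_root_cache = cache
        return self._comp_root_cache[v]

    def same_component(self, *vs: str) -> bool:
        roots = {self.component_root(v) for v in vs}
        return len(roots) == 1

    def forest_leaves(self, v: str) -> list[str]:
        """Gene-tree leaves reachable from v without crossing a transfer edge."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.tree.is_leaf(u):
                out.append(u)
                continue
            for c in self.tree.children(u):
                if (u, c) not in self.transfer_edges:
                    stack.append(c)
        return out

    def sigma_forest(self, v: str) -> frozenset[str]:
        """sigma_{T_E}(v): species of leaves reachable within v's component."""
        if v not in self.tree.vertices:
            raise ValueError(f"unknown vertex {v!r}")
        if self._sigma_forest_cache is None:
            cache: dict[str, frozenset[str]] = {}
            for u in self.tree.postorder():
                if self.tree.is_leaf(u):
                    cache[u] = frozenset((self.sigma[u],))
                else:
                    acc: set[str] = set()
                    for c in self.tree.children(u):
                        if (u, c) not in self.transfer_edges:
                            acc |= cache[c]
                    cache[u] = frozenset(acc)
            self._sigma_forest_cache = cache
        return self._sigma_forest_cache[v]

    def transfer_forest(self) -> "TransferForest":
        return transfer_forest(self)

    # -- validation ---------------------------------------------------------

    def validate_observability(self) -> list[str]:
        return validate_observability(self)

    def is_valid(self) -> bool:
        return not self.validate_observability()

    def to_nhx(self) -> str:
        return write_labeled_gene_tree(self)


@dataclass
class TransferForest:
    """Connected components of the transfer-free forest T_E."""

    components: list[RootedTree]
    component_of: dict[str, int] = field(repr=False)
    component_root: dict[int, str] = field(repr=False)


def transfer_forest(gt: EventLabeledGeneTree) -> TransferForest:
    """Split T at its transfer edges; k transfer edges yield k+1 components."""
    roots: list[str] = []
    for v in gt.tree.preorder():
        if gt.component_root(v) == v:
            roots.append(v)
    components: list[RootedTree] = []
    component_of: dict[str, int] = {}
    component_root: dict[int, str] = {}
    for idx, r in enumerate(roots):
        children: dict[str, list[str]] = {}
        leaf_label: dict[str, str] = {}
        stack = [r]
        while stack:
            u = stack.pop()
            component_of[u] = idx
            if gt.tree.is_leaf(u):
                leaf_label[u] = gt.tree.leaf_label[u]
                continue
            kids = [
                c for c in gt.tree.children(u) if (u, c) not in gt.transfer_edges
            ]
            children[u] = kids
            stack.extend(kids)
        components.append(RootedTree(r, children, leaf_label))
        component_root[idx] = r
    return TransferForest(components, component_of, component_root)


def validate_observability(gt: EventLabeledGeneTree) -> list[str]:
    """Check the observability axioms; violations are returned, not raised.

    O1: every internal vertex has out-degree at least 2.
    O2: every transfer vertex has at least one transfer and one
        non-transfer out-edge.
    O3a: the children of a speciation have pairwise disjoint
         transfer-free species sets.
    O3b: the two endpoints of a transfer edge have disjoint
         transfer-free species sets.
    """
    violations: list[str] = []
    tree = gt.tree
    for v in tree.preorder():
        if tree.is_leaf(v):
            continue
        ch = tree.children(v)
        if len(ch) < 2:
            violations.append(f"O1: internal vertex {v} has out-degree {len(ch)}")
        ev = gt.event[v]
        if ev == TRANSFER:
            n_transfer = sum(1 for c in ch if (v, c) in gt.transfer_edges)
            if n_transfer == 0:
                violations.append(f"O2: transfer vertex {v} has no transfer edge")
            if n_transfer == len(ch):
                violations.append(f"O2: transfer vertex {v} has no non-transfer edge")
        if ev == SPECIATION:
            for i in range(len(ch)):
                for j in range(i + 1, len(ch)):
                    shared = gt.sigma_forest(ch[i]) & gt.sigma_forest(ch[j])
                    if shared:
                        violations.append(
                            f"O3a: speciation {v} children {ch[i]},{ch[j]} share "
                            f"species {sorted(shared)}"
                        )
    for (x, y) in sorted(gt.transfer_edges):
        shared = gt.sigma_forest(x) & gt.sigma_forest(y)
        if shared:
            violations.append(
                f"O3b: transfer edge ({x},{y}) endpoints share species {sorted(shared)}"
            )
    return violations


# -- NHX I/O ----------------------------------------------------------------


def _parse_nhx_comment(comments: list[str], where: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for comment in comments:
        body = comment.strip()
        if not body.startswith("&&NHX"):
            continue
        body = body[len("&&NHX") :].lstrip(":")
        for item in body.split(":"):
            if not item:
                continue
            if "=" not in item:
                raise FormatError(f"bad NHX item {item!r} at {where}")
            k, _, v = item.partition("=")
            out[k] = v
    return out


def read_labeled_gene_tree(
    newick_text: str, species_map: Optional[dict[str, str]] = None
) -> EventLabeledGeneTree:
    """Read an NHX-annotated gene tree.

    ``species_map`` (gene label -> species) supplements or overrides the
    per-leaf ``S=`` tags.  The result is syntactically validated only; run
    :func:`validate_observability` to check the observability axioms.
    """
    text = newick_text.strip()
    if not text.endswith(";"):
        raise ParseError("Newick string must end in ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc
    tree, nodes = _from_dendropy(dtree)
    event: dict[str, str] = {}
    transfer_edges: set[tuple[str, str]] = set()
    sigma: dict[str, str] = {}
    for vid, nd in nodes.items():
        tags = _parse_nhx_comment(nd.comments, f"vertex {vid}")
        if tree.is_leaf(vid):
            sp = tags.get("S")
            if species_map and tree.leaf_label[vid] in species_map:
                sp = species_map[tree.leaf_label[vid]]
            if sp is None:
                raise FormatError(f"leaf {tree.leaf_label[vid]!r} has no species")
            sigma[vid] = sp
        else:
            ev = tags.get("ev")
            if ev not in _INTERNAL_EVENTS:
                raise FormatError(
                    f"internal vertex {vid!r} lacks a valid ev= tag (got {ev!r})"
                )
            event[vid] = ev
        if tags.get("xfer") == "1":
            parent = tree.parent.get(vid)
            if parent is None:
                raise FormatError("xfer=1 on the root vertex")
            transfer_edges.add((parent, vid))
    gt = EventLabeledGeneTree(tree, event, transfer_edges, sigma)
    return gt


def write_labeled_gene_tree(gt: EventLabeledGeneTree) -> str:
    """Render the gene tree as NHX-annotated Newick (inverse of the reader)."""
    tree = gt.tree

    def render(v: str) -> str:
        tags: list[str] = []
        if tree.is_leaf(v):
            base = tree.leaf_label[v]
            tags.append(f"S={gt.sigma[v]}")
        else:
            base = "(" + ",".join(render(c) for c in tree.children(v)) + ")"
            tags.append(f"ev={gt.event[v]}")
        p = tree.parent.get(v)
        if p is not None and (p, v) in gt.transfer_edges:
            tags.append("xfer=1")
        return base + "[&&NHX:" + ":".join(tags) + "]"

    return render(tree.root) + ";"


def read_species_map(text: str) -> dict[str, str]:
    """Parse a two-column TSV (gene TAB species, no header)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"species map line {lineno}: expected 2 columns")
        out[parts[0]] = parts[1]
    return out
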