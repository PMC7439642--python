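"""Rooted phylogenetic trees, Newick I/O, and rooted-triplet machinery.

All trees are rooted with edges directed away from the root.  Vertices are
opaque string ids; leaves carry unique string labels (gene or species
names).  The internal order of children is canonical -- sorted by the
smallest leaf label in the subtree -- so every derived output (Newick
strings, traversals, tie-breaks in the solver) is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import dendropy


class ParseError(ValueError):
    """Raised for malformed Newick input."""


class Triplet(NamedTuple):
    """A rooted triplet ab|c: the pair {a, b} is separated from outgroup c.

    Stored with the pair normalized lexicographically, so ab|c == ba|c.
    """

    a: str
    b: str
    c: str

    @classmethod
    def of(cls, a: str, b: str, c: str) -> "Triplet":
        if a == b or a == c or b == c:
            raise ValueError(f"triplet labels must be pairwise distinct: {a},{b},{c}")
        if b < a:
            a, b = b, a
        return cls(a, b, c)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a},{self.b}|{self.c}"


class RootedTree:
    """A rooted tree with opaque vertex ids and labeled leaves."""

    __slots__ = (
        "root",
        "_children",
        "parent",
        "leaf_label",
        "_min_label",
        "_depth",
        "_label2leaf",
    )

    def __init__(
        self,
        root: str,
        children: dict[str, Sequence[str]],
        leaf_label: dict[str, str],
    ):
        self.root = root
        self.leaf_label = dict(leaf_label)
        ch = {v: list(c) for v, c in children.items()}
        # sanity: every vertex reachable exactly once from the root
        parent: dict[str, str] = {}
        seen = {root}
        stack = [root]
        while stack:
            v = stack.pop()
            for c in ch.get(v, ()):
                if c in seen:
                    raise ValueError(f"vertex {c!r} has two parents or a cycle")
                seen.add(c)
                parent[c] = v
                stack.append(c)
        extra = set(ch) - seen
        if extra:
            raise ValueError(f"vertices not reachable from root: {sorted(extra)}")
        for v in seen:
            if not ch.get(v) and v not in self.leaf_label:
                raise ValueError(f"leaf vertex {v!r} has no label")
        labels = list(self.leaf_label.values())
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels are not unique")
        self.parent = parent
        self._children = ch
        # canonical child order: by smallest descendant leaf label
        self._min_label: dict[str, str] = {}
        for v in self.postorder():
            if self.is_leaf(v):
                self._min_label[v] = self.leaf_label[v]
            else:
                self._min_label[v] = min(self._min_label[c] for c in self._children[v])
        for v in ch:
            ch[v].sort(key=lambda c: self._min_label[c])
        self._depth: dict[str, int] = {root: 0}
        for v in self.preorder():
            for c in self._children.get(v, ()):
                self._depth[c] = self._depth[v] + 1
        self._label2leaf = {lab: v for v, lab in self.leaf_label.items()}

    # -- basic queries ----------------------------------------------------

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(self._children.get(v, ()))

    def is_leaf(self, v: str) -> bool:
        return not self._children.get(v)

    @property
    def vertices(self) -> set[str]:
        return set(self._depth)

    def edges(self) -> Iterator[tuple[str, str]]:
        for v in self.preorder():
            for c in self._children.get(v, ()):
                yield (v, c)

    def leaves(self) -> list[str]:
        return [v for v in self.preorder() if self.is_leaf(v)]

    def leaf_labels(self) -> set[str]:
        return set(self.leaf_label.values())

    def leaf_by_label(self, label: str) -> str:
        return self._label2leaf[label]

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self._children.get(v, ())))

    def postorder(self) -> Iterator[str]:
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children.get(v, ()))
        return reversed(out)

    def subtree_leaves(self, v: str) -> list[str]:
        return [u for u in self._subtree(v) if self.is_leaf(u)]

    def _subtree(self, v: str) -> Iterator[str]:
        stack = [v]
        while stack:
            u = stack.pop()
            yield u
            stack.extend(self._children.get(u, ()))

    # -- ancestor relations -----------------------------------------------

    def is_ancestor(self, x: str, y: str) -> bool:
        """True iff x is an ancestor of y (reflexively: y <= x)."""
        while self._depth[y] > self._depth[x]:
            y = self.parent[y]
        return x == y

    def comparable(self, x: str, y: str) -> bool:
        return self.is_ancestor(x, y) or self.is_ancestor(y, x)

    def lca(self, X: Iterable[str]) -> str:
        """Lowest common ancestor of a nonempty set of vertex ids."""
        it = iter(X)
        try:
            v = next(it)
        except StopIteration:
            raise ValueError("lca of an empty set is undefined") from None
        if v not in self._depth:
            raise ValueError(f"unknown vertex {v!r}")
        for u in it:
            if u not in self._depth:
                raise ValueError(f"unknown vertex {u!r}")
            while self._depth[u] > self._depth[v]:
                u = self.parent[u]
            while self._depth[v] > self._depth[u]:
                v = self.parent[v]
            while u != v:
                u = self.parent[u]
                v = self.parent[v]
        return v

    def lca_labels(self, labels: Iterable[str]) -> str:
        return self.lca(self.leaf_by_label(lab) for lab in labels)

    # -- shape predicates ---------------------------------------------------

    def is_binary(self) -> bool:
        return all(len(self.children(v)) == 2 for v in self._depth if not self.is_leaf(v))

    def is_almost_binary(self) -> bool:
        """True iff every non-binary vertex is a cherry (all children leaves)."""
        for v in self._depth:
            if self.is_leaf(v):
                continue
            ch = self.children(v)
            if len(ch) != 2 and not all(self.is_leaf(c) for c in ch):
                return False
        return True

    def cherries(self) -> list[str]:
        """Internal vertices whose children are all leaves, in canonical order."""
        out = [
            v
            for v in self._depth
            if not self.is_leaf(v) and all(self.is_leaf(c) for c in self.children(v))
        ]
        out.sort(key=lambda v: self._min_label[v])
        return out

    # -- triplets ----------------------------------------------------------

    def displays(self, t: Triplet) -> bool:
        la = self.leaf_by_label(t.a)
        lb = self.leaf_by_label(t.b)
        lc = self.leaf_by_label(t.c)
        ab = self.lca([la, lb])
        abc = self.lca([ab, lc])
        return ab != abc

    def displayed_triplets(self) -> set[Triplet]:
        """All rooted triplets rt(T): ab|c with lca(a,b) strictly below lca(a,b,c)."""
        leaves = self.leaves()
        out: set[Triplet] = set()
        for i, x in enumerate(leaves):
            for y in leaves[i + 1 :]:
                anc = self.lca([x, y])
                for z in leaves:
                    if z is x or z is y:
                        continue
                    if self.lca([anc, z]) != anc:
                        out.add(Triplet.of(self.leaf_label[x], self.leaf_label[y], self.leaf_label[z]))
        return out

    def agrees(self, R: Iterable[Triplet]) -> bool:
        """True iff no contradiction ac|b or bc|a of any ab|c in R is displayed."""
        for t in R:
            missing = {t.a, t.b, t.c} - self.leaf_labels()
            if missing:
                raise ValueError(f"labels absent from tree: {sorted(missing)}")
            if self.displays(Triplet.of(t.a, t.c, t.b)) or self.displays(
                Triplet.of(t.b, t.c, t.a)
            ):
                return False
        return True

    # -- construction and surgery ------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return read_newick(text)

    def to_newick(self) -> str:
        def render(v: str) -> str:
            if self.is_leaf(v):
                return self.leaf_label[v]
            return "(" + ",".join(render(c) for c in self.children(v)) + ")"

        return render(self.root) + ";"

    def copy(self) -> "RootedTree":
        return RootedTree(self.root, self._children, self.leaf_label)

    def fresh_vertex_id(self) -> str:
        i = len(self._depth)
        while f"v{i}" in self._depth:
            i += 1
        return f"v{i}"

    def apply_extension(self, x: str, Xp: Iterable[str]) -> "RootedTree":
        """Insert a new vertex between x and the strict child subset Xp.

        With |Xp| <= 1 the tree is returned unchanged.  Xp must be a strict
        subset of the children of x, and x must have at least 3 children.
        """
        Xp = list(dict.fromkeys(Xp))
        ch = list(self.children(x))
        if len(ch) < 3:
            raise ValueError(f"extension requires >= 3 children at {x!r}")
        if not set(Xp) < set(ch) or not Xp:
            raise ValueError("Xp must be a nonempty strict subset of ch(x)")
        if len(Xp) <= 1:
            return self.copy()
        y = self.fresh_vertex_id()
        children = {v: list(c) for v, c in self._children.items()}
        children[x] = [c for c in ch if c not in set(Xp)] + [y]
        children[y] = Xp
        return RootedTree(self.root, children, self.leaf_label)

    def restrict(self, X: Iterable[str]) -> "RootedTree":
        """Restriction T|_X to a nonempty subset X of leaf labels."""
        X = set(X)
        if not X:
            raise ValueError("restriction to an empty label set")
        missing = X - self.leaf_labels()
        if missing:
            raise ValueError(f"unknown leaf labels: {sorted(missing)}")
        keep_leaves = {v for v in self.leaves() if self.leaf_label[v] in X}
        # count leaves of X below each vertex; keep vertices covering >= 1
        count: dict[str, int] = {}
        for v in self.postorder():
            if self.is_leaf(v):
                count[v] = 1 if v in keep_leaves else 0
            else:
                count[v] = sum(count[c] for c in self.children(v))
        # build the minimal subtree, suppressing out-degree-1 chains
        def build(v: str) -> str:
            while not self.is_leaf(v):
                kept = [c for c in self.children(v) if count[c] > 0]
                if len(kept) != 1:
                    return v
                v = kept[0]
            return v

        root = build(self.root)
        children: dict[str, list[str]] = {}
        leaf_label: dict[str, str] = {}
        stack = [root]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                leaf_label[v] = self.leaf_label[v]
                continue
            sub = [build(c) for c in self.children(v) if count[c] > 0]
            children[v] = sub
            stack.extend(sub)
        return RootedTree(root, children, leaf_label)

    def same_topology(self, other: "RootedTree") -> bool:
        """Label-preserving isomorphism (vertex ids are ignored)."""
        return self.to_newick() == other.to_newick()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RootedTree({self.to_newick()!r})"


def read_newick(text: str) -> RootedTree:
    """Parse a single rooted Newick string into a RootedTree.

    Internal vertex ids are assigned "v0", "v1", ... in depth-first order
    with children in file order; leaf ids equal their labels.  Branch
    lengths, if present, are parsed and ignored.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise ParseError(f"Newick string must end in ';' (got {text[-10:]!r})")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)[0]


def _from_dendropy(dtree: "dendropy.Tree") -> tuple[RootedTree, dict[str, "dendropy.Node"]]:
    """Convert a dendropy tree; also return vertex id -> dendropy node."""
    children: dict[str, list[str]] = {}
    leaf_label: dict[str, str] = {}
    nodes: dict[str, dendropy.Node] = {}
    counter = 0
    seen_labels: set[str] = set()

    def visit(nd: "dendropy.Node") -> str:
        nonlocal counter
        kids = nd.child_nodes()
        if not kids:
            label = None
            if nd.taxon is not None:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            if not label:
                raise ParseError("leaf without a label")
            if label in seen_labels:
                raise ParseError(f"duplicate leaf label {label!r}")
            seen_labels.add(label)
            leaf_label[label] = label
            nodes[label] = nd
            return label
        vid = f"v{counter}"
        counter += 1
        nodes[vid] = nd
        children[vid] = [visit(k) for k in kids]
        return vid

    root = visit(dtree.seed_node)
    if not leaf_label:
        raise ParseError("empty tree")
    return RootedTree(root, children, leaf_label), nodes


def star_tree(labels: Iterable[str]) -> RootedTree:
    """The star tree over a set of leaf labels (single-leaf trees allowed)."""
    labels = sorted(set(labels))
    if not labels:
        raise ValueError("star tree over an empty label set")
    if len(labels) == 1:
        return RootedTree(labels[0], {}, {labels[0]: labels[0]})
    return RootedTree("v0", {"v0": labels}, {lab: lab for lab in labels})


def forest_displayed_triplets(components: Sequence[RootedTree]) -> set[Triplet]:
    """Triplets displayed by a forest: displayed by one of its components."""
    out: set[Triplet] = set()
    for comp in components:
        out |= comp.displayed_triplets()
    return out
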