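"""Phylogenetic tree data model, Newick I/O and split machinery.

Trees are stored rooted (as parsed) but every bipartition/quadripartition
operation works on the unrooted view: a degree-2 root is suppressed and the
two root edges merged. Concordance between gene trees and a reference tree
is a property of unrooted splits, so this is the natural frame for all the
downstream statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import dendropy


class NewickError(ValueError):
    """Raised for malformed Newick input or invariant violations."""


class Node:
    """A tree node. ``label`` is the taxon name for leaves; ``support`` holds
    an opaque real support annotation (LPP/BS) read from internal labels."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))


class Tree:
    """Rooted container for a phylogeny with unique leaf labels.

    Branch lengths (when present) must be non-negative; internal nodes may be
    polytomous (gene trees commonly are).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        labels = []
        for nd in self.root.postorder():
            if nd.is_leaf:
                if not nd.label:
                    raise NewickError("every leaf must carry a non-empty label")
                labels.append(nd.label)
            if nd.length is not None and nd.length < 0:
                raise NewickError(
                    f"negative branch length {nd.length} on node {nd.label!r}"
                )
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
        self._leaf_labels = frozenset(labels)

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string (bracketed comments tolerated and ignored)."""
        if not text or not text.strip():
            raise NewickError("empty Newick input")
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(_from_dendropy(dt))

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset:
        return self._leaf_labels

    def leaves(self) -> list[Node]:
        return [nd for nd in self.root.postorder() if nd.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def copy(self) -> "Tree":
        def rec(nd: Node) -> Node:
            new = Node(nd.label, nd.length, nd.support)
            for c in nd.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root))

    def polytomies(self) -> list[Node]:
        """Internal nodes with more than two children (root: more than three
        neighbours in the unrooted sense, i.e. >3 children, or >2 if it also
        has a parent edge, which a root never does)."""
        out = []
        for nd in self.root.postorder():
            if nd.is_leaf:
                continue
            limit = 3 if nd is self.root else 2
            if len(nd.children) > limit:
                out.append(nd)
        return out

    def is_binary_unrooted(self) -> bool:
        if self.n_leaves < 3:
            return True
        if self.polytomies():
            return False
        # a rooted-binary or basal-trifurcation representation is fine
        return len(self.root.children) in (2, 3)

    # -- splits ------------------------------------------------------------

    def split_sides(self) -> frozenset:
        """All label-sets induced by edges of the unrooted tree, with *both*
        sides of every split included (fast membership tests for induced
        bipartitions). Trivial splits are included; the full set is not."""
        universe = self._leaf_labels
        sides = set()
        for nd in self.root.postorder():
            if nd is self.root:
                continue
            below = _clade_cache(nd)
            if 0 < len(below) < len(universe):
                sides.add(below)
                sides.add(universe - below)
        return frozenset(sides)

    def clades(self) -> dict:
        """Map each non-root node to the frozenset of labels below it."""
        out = {}
        for nd in self.root.postorder():
            if nd is self.root:
                continue
            out[nd] = _clade_cache(nd)
        return out

    # -- editing -----------------------------------------------------------

    def prune(self, drop: Iterable[str]) -> "Tree":
        """Return a new tree with the given leaves removed and resulting
        unifurcations suppressed (lengths summed)."""
        drop = set(drop)
        kept = self._leaf_labels - drop
        if len(kept) < 2:
            raise ValueError("pruning would leave fewer than two leaves")

        def rec(nd: Node) -> Optional[Node]:
            if nd.is_leaf:
                if nd.label in drop:
                    return None
                return Node(nd.label, nd.length, nd.support)
            children = [rec(c) for c in nd.children]
            children = [c for c in children if c is not None]
            if not children:
                return None
            if len(children) == 1:
                child = children[0]
                if nd.length is not None or child.length is not None:
                    child.length = (nd.length or 0.0) + (child.length or 0.0)
                return child
            new = Node(nd.label, nd.length, nd.support)
            for c in children:
                new.add_child(c)
            return new

        root = rec(self.root)
        assert root is not None
        if len(root.children) == 1:  # collapse degenerate root
            root = root.children[0]
            root.parent = None
        return Tree(root)

    def scaled(self, factor: float) -> "Tree":
        """Return a copy with every branch length multiplied by ``factor``."""
        new = self.copy()
        for nd in new.root.postorder():
            if nd.length is not None:
                nd.length = nd.length * factor
        return new

    # -- output ------------------------------------------------------------

    def write_newick(self, lengths: bool = True, supports: bool = True) -> str:
        buf = io.StringIO()

        def rec(nd: Node) -> None:
            if nd.is_leaf:
                buf.write(_quote(nd.label))
            else:
                buf.write("(")
                for i, c in enumerate(nd.children):
                    if i:
                        buf.write(",")
                    rec(c)
                buf.write(")")
                if supports and nd.support is not None:
                    buf.write(_fmt(nd.support))
                elif nd.label:
                    buf.write(_quote(nd.label))
            if lengths and nd.length is not None:
                buf.write(":" + _fmt(nd.length))

        rec(self.root)
        buf.write(";")
        return buf.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.n_leaves} leaves)"


def _fmt(x: float) -> str:
    return repr(x) if isinstance(x, float) else str(x)  # shortest round-trip


_SAFE_LABEL = set(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-|"
)


def _quote(label: str) -> str:
    if set(label) <= _SAFE_LABEL:
        return label
    return "'" + label.replace("'", "''") + "'"


_CLADE_ATTR = {}


def _clade_cache(nd: Node) -> frozenset:
    # recompute each call tree-wide: cached per postorder pass via children
    if nd.is_leaf:
        return frozenset((nd.label,))
    out = set()
    stack = [nd]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.add(cur.label)
        else:
            stack.extend(cur.children)
    return frozenset(out)


def _from_dendropy(dt: "dendropy.Tree") -> Node:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            nd = Node(label=label, length=dnode.edge.length)
        else:
            support = None
            label = dnode.label
            if label is not None:
                try:
                    support = float(label)
                    label = None
                except (TypeError, ValueError):
                    pass
            nd = Node(label=label, length=dnode.edge.length, support=support)
            for c in dnode.child_nodes():
                nd.add_child(convert(c))
        return nd

    return convert(dt.seed_node)


def parse_newick(text: str) -> Tree:
    """Parse one Newick description into a :class:`Tree`."""
    return Tree.from_newick(text)


def read_newick_list(path) -> list[Tree]:
    """Read one Newick tree per line (blank lines skipped)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(Tree.from_newick(line))
    return trees


def write_newick_list(trees: Sequence[Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.write_newick() + "\n")


# ---------------------------------------------------------------------------
# quadripartitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Quadripartition:
    """The four taxon blocks around an internal branch of a binary reference
    tree. The reference resolution is AB|CD; the nearest-neighbour
    alternatives are AC|BD (labelled DF1) and AD|BC (labelled DF2).

    Canonical ordering: the side containing the globally smallest taxon label
    supplies (A, B); within each side the block containing the
    lexicographically smallest label comes first. This pins down the DF1/DF2
    labels, which the underlying statistics leave arbitrary.
    """

    a: frozenset
    b: frozenset
    c: frozenset
    d: frozenset

    @property
    def universe(self) -> frozenset:
        return self.a | self.b | self.c | self.d

    @property
    def main_side(self) -> frozenset:
        return self.a | self.b

    @classmethod
    def canonical(cls, side1, side2) -> "Quadripartition":
        """Build from the raw blocks: side1/side2 are pairs of blocks on the
        two endpoints of the branch."""

        def order(side):
            x, y = side
            return (x, y) if min(x) < min(y) else (y, x)

        s1, s2 = order(side1), order(side2)
        if min(min(s1[0]), min(s1[1])) < min(min(s2[0]), min(s2[1])):
            a, b = s1
            c, d = s2
        else:
            a, b = s2
            c, d = s1
        return cls(frozenset(a), frozenset(b), frozenset(c), frozenset(d))


class _Adjacency:
    """Unrooted adjacency view of a Tree (degree-2 root suppressed)."""

    def __init__(self, tree: Tree):
        self.tree = tree
        self.adj: dict = {}
        self.label: dict = {}
        nodes = list(tree.root.postorder())
        for nd in nodes:
            self.adj[id(nd)] = []
            if nd.is_leaf:
                self.label[id(nd)] = nd.label
        root = tree.root
        suppress = len(root.children) == 2 and root.parent is None
        for nd in nodes:
            for c in nd.children:
                if suppress and nd is root:
                    continue
                self._connect(id(nd), id(c), c.length)
        if suppress:
            l, r = root.children
            length = None
            if l.length is not None or r.length is not None:
                length = (l.length or 0.0) + (r.length or 0.0)
            self._connect(id(l), id(r), length)
        self._node_by_id = {id(nd): nd for nd in nodes}

    def _connect(self, u, v, length):
        self.adj[u].append((v, length))
        self.adj[v].append((u, length))

    def degree(self, u) -> int:
        return len(self.adj[u])

    def side_leaves(self, start, avoid) -> frozenset:
        """Leaf labels reachable from ``start`` without crossing ``avoid``."""
        seen = {avoid, start}
        out = set()
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur in self.label:
                out.add(self.label[cur])
            for nbr, _ in self.adj[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def internal_edges(self):
        """Edges whose endpoints are both internal, deduplicated, with
        lengths. Returns list of (u, v, length)."""
        out = []
        seen = set()
        for u, nbrs in self.adj.items():
            for v, length in nbrs:
                if (v, u) in seen or (u, v) in seen:
                    continue
                seen.add((u, v))
                if u not in self.label and v not in self.label:
                    out.append((u, v, length))
        return out


@dataclass(frozen=True)
class Branch:
    """An internal branch of a reference tree, identified by its split."""

    split: frozenset  # the side NOT containing the smallest taxon label
    length: Optional[float]
    quadripartition: Quadripartition

    @property
    def branch_id(self) -> str:
        return ",".join(sorted(self.split))


def _quadripartition_from_edge(adj: _Adjacency, u, v) -> Quadripartition:
    def blocks(endpoint, other):
        nbrs = [(n, l) for n, l in adj.adj[endpoint] if n != other]
        if len(nbrs) != 2:
            raise ValueError(
                "quadripartition requires strictly bifurcating branch "
                f"endpoints; endpoint has {len(nbrs) + 1} neighbours"
            )
        return [adj.side_leaves(n, endpoint) for n, _ in nbrs]

    return Quadripartition.canonical(blocks(u, v), blocks(v, u))


def reference_branches(tree: Tree, strict: bool = True) -> list[Branch]:
    """Enumerate internal branches of the (unrooted) reference tree with
    their quadripartitions.

    ``strict=True`` raises on polytomous branch endpoints; otherwise such
    branches are silently skipped (they admit no quadripartition).
    """
    adj = _Adjacency(tree)
    smallest = min(tree.leaf_labels)
    out = []
    for u, v, length in adj.internal_edges():
        try:
            q = _quadripartition_from_edge(adj, u, v)
        except ValueError:
            if strict:
                raise
            continue
        side1 = q.a | q.b
        split = side1 if smallest not in side1 else q.c | q.d
        out.append(Branch(split=split, length=length, quadripartition=q))
    out.sort(key=lambda b: sorted(b.split))
    return out


def quadripartition(tree: Tree, split) -> Quadripartition:
    """Quadripartition around the internal branch identified by ``split``
    (a set of leaf labels on one side of the branch).

    Raises for terminal branches and polytomous endpoints.
    """
    split = frozenset(split)
    universe = tree.leaf_labels
    if len(split) < 2 or len(universe - split) < 2:
        raise ValueError("no quadripartition for terminal branch")
    for br in reference_branches(tree, strict=True):
        if br.split == split or br.split == universe - split:
            return br.quadripartition
    raise ValueError(f"no internal branch with split {sorted(split)}")


# ---------------------------------------------------------------------------
# gene-tree classification
# ---------------------------------------------------------------------------


class GeneTreeCategory(Enum):
    CONCORDANT = "concordant"
    DF1 = "df1"
    DF2 = "df2"
    PARAPHYLY = "paraphyly"
    NOT_DECISIVE = "not_decisive"


def classify_gene_tree(
    gene: Tree,
    q: Quadripartition,
    _sides: Optional[frozenset] = None,
) -> GeneTreeCategory:
    """Classify a gene tree against a reference-branch quadripartition.

    A gene tree is decisive for the branch iff it samples at least one taxon
    from each of the four blocks. A decisive tree is CONCORDANT if one of its
    branches induces the reference bipartition (A∪B | C∪D) restricted to its
    own leaves, DF1/DF2 for the two nearest-neighbour alternatives, and
    PARAPHYLY otherwise.
    """
    leaves = gene.leaf_labels
    unknown = leaves - q.universe
    if unknown:
        raise ValueError(
            f"gene-tree labels outside the reference taxon set: {sorted(unknown)}"
        )
    for block in (q.a, q.b, q.c, q.d):
        if not (block & leaves):
            return GeneTreeCategory.NOT_DECISIVE
    sides = _sides if _sides is not None else gene.split_sides()
    if ((q.a | q.b) & leaves) in sides:
        return GeneTreeCategory.CONCORDANT
    if ((q.a | q.c) & leaves) in sides:
        return GeneTreeCategory.DF1
    if ((q.a | q.d) & leaves) in sides:
        return GeneTreeCategory.DF2
    return GeneTreeCategory.PARAPHYLY
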