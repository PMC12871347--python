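"""Rooted binary phylogenies rooted in a leaf.

The tree structure used throughout this package is a binary topology whose
root is a *leaf*: the root node carries a taxon label and has exactly one
child, and every other internal node has exactly two children.  Rooting in a
leaf gives every non-root node exactly one incoming edge, so an edge can be
identified by its child-side node.  Nodes are numbered by a preorder
traversal (parents before children), which makes tensor layouts reproducible.

Children are ordered by the smallest leaf label in their subtree, so a
topology has a single canonical node numbering.

Newick strings are parsed with :mod:`dendropy` and converted into this
structure; arbitrary (unrooted or internally rooted) binary Newick input is
re-rooted at a leaf, by default the lexicographically smallest label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "RootedTree",
    "Split",
    "TreeError",
    "parse_newick",
    "write_newick",
    "root_at_leaf",
    "internal_edges",
    "split_of_edge",
    "random_topology",
    "sample_rooted_shape",
]


class TreeError(ValueError):
    """Raised for malformed or invalid tree input."""


class TreeNode:
    """A node of a :class:`RootedTree`.

    Attributes
    ----------
    index : int
        Preorder index (root is 0; every parent index < child index).
    parent : TreeNode or None
        ``None`` for the root.
    children : list of TreeNode
        Empty for leaves; two entries for non-root internal nodes; one for
        the (leaf) root.
    label : str
        Taxon label; nonempty exactly for leaves (including the root).
    length : float or None
        Branch length of the incoming edge (ignored by all parsimony and
        model computations; preserved for I/O).
    """

    __slots__ = ("index", "parent", "children", "label", "length")

    def __init__(self, label: str = "", length: Optional[float] = None):
        self.index: int = -1
        self.parent: Optional["TreeNode"] = None
        self.children: list["TreeNode"] = []
        self.label = label
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        kind = "leaf" if self.is_leaf else "internal"
        return f"<TreeNode {self.index} {kind} {self.label!r}>"


@dataclass(frozen=True)
class Split:
    """A bipartition of the leaf set induced by deleting an edge.

    ``side_a`` is the canonical side: the one containing the
    lexicographically smallest leaf label.  Equality and hashing use both
    sides, so splits from trees over different leaf sets never collide
    silently.
    """

    side_a: frozenset
    side_b: frozenset

    @staticmethod
    def of(side: Iterable[str], all_labels: Iterable[str]) -> "Split":
        side = frozenset(side)
        universe = frozenset(all_labels)
        if not side or not side <= universe or side == universe:
            raise TreeError("split side must be a proper nonempty subset of the leaf set")
        other = universe - side
        smallest = min(universe)
        if smallest in side:
            return Split(side, other)
        return Split(other, side)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1

    def __str__(self) -> str:
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"{a}|{b}"


class RootedTree:
    """A binary phylogeny rooted in a leaf, with canonical preorder indices.

    Construct via :func:`parse_newick`, :func:`random_topology`, or from a
    linked :class:`TreeNode` structure (``RootedTree(root_node)``); the
    constructor sorts children by smallest descendant leaf label, assigns
    preorder indices, and validates the shape invariants.
    """

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        self.nodes: list[TreeNode] = []
        self._canonicalize()
        if validate:
            self.validate()

    # -- construction helpers ------------------------------------------------

    def _canonicalize(self) -> None:
        min_label: dict[int, str] = {}

        def _min_label(node: TreeNode) -> str:
            if node.is_leaf:
                m = node.label
            else:
                m = min(_min_label(c) for c in node.children)
            min_label[id(node)] = m
            return m

        _min_label(self.root)

        self.nodes = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            node.children.sort(key=lambda c: min_label[id(c)])
            stack.extend(reversed(node.children))

    def validate(self) -> None:
        if not self.root.is_leaf and len(self.root.children) != 1:
            raise TreeError("root must be a leaf: exactly one child")
        if self.root.children and not self.root.label:
            raise TreeError("root must carry a leaf label")
        labels = []
        for node in self.nodes:
            if node.is_leaf or node is self.root:
                if not node.label:
                    raise TreeError("leaf with empty label")
                labels.append(node.label)
            elif len(node.children) != 2:
                raise TreeError(
                    f"non-root internal node with {len(node.children)} children (tree must be binary)"
                )
            if node.parent is not None and node.parent.index >= node.index:
                raise TreeError("node indices are not a preorder numbering")
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")

    # -- basic queries -------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def leaves(self) -> list[TreeNode]:
        # The root counts as a leaf when it carries a taxon label.
        return [n for n in self.nodes if n.is_leaf or (n is self.root and n.label)]

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves)

    def node_by_label(self, label: str) -> TreeNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise TreeError(f"no leaf labeled {label!r}")

    def postorder(self) -> Iterator[TreeNode]:
        def _walk(node: TreeNode) -> Iterator[TreeNode]:
            for c in node.children:
                yield from _walk(c)
            yield node

        return _walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        return iter(self.nodes)

    def leaves_below(self, node: TreeNode) -> frozenset:
        acc = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v.is_leaf:
                acc.append(v.label)
            stack.extend(v.children)
        return frozenset(acc)

    def depth(self) -> int:
        """Maximum edge count from the root to any leaf."""

        best = 0
        stack = [(self.root, 0)]
        while stack:
            v, d = stack.pop()
            if v.is_leaf:
                best = max(best, d)
            for c in v.children:
                stack.append((c, d + 1))
        return best

    # -- splits --------------------------------------------------------------

    def internal_splits(self) -> frozenset:
        """The set of nontrivial splits (one per internal edge)."""

        return frozenset(
            split_of_edge(self, v) for v in internal_edges(self, "preorder")
        )

    def topology_key(self) -> frozenset:
        """Canonical identity of the unrooted topology: leaf set + splits."""

        return frozenset([("leaves", frozenset(self.leaf_labels))]) | frozenset(
            ("split", s) for s in self.internal_splits()
        )

    def copy(self) -> "RootedTree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add_child(_clone(c))
            return new

        return RootedTree(_clone(self.root), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedTree n_leaves={self.n_leaves} root={self.root.label!r}>"


# ---------------------------------------------------------------------------
# Edge queries
# ---------------------------------------------------------------------------


def internal_edges(tree: RootedTree, order: str = "postorder") -> list[TreeNode]:
    """Internal edges of *tree*, each identified by its child-side node.

    An internal edge has internal nodes at both endpoints; since the root is
    a leaf, these are exactly the nodes with children whose parent is not the
    root.  There are ``n_leaves - 3`` of them for ``n_leaves >= 4``.

    ``order="postorder"`` lists every edge after both edges below it;
    ``order="preorder"`` lists every edge after its parent edge.
    """

    if order not in ("postorder", "preorder"):
        raise ValueError(f"unknown order {order!r}")
    walk = tree.postorder() if order == "postorder" else tree.preorder()
    return [
        v
        for v in walk
        if v.children and v.parent is not None and v.parent is not tree.root
    ]


def split_of_edge(tree: RootedTree, edge: TreeNode) -> Split:
    """The split induced by deleting the edge above *edge* (child-side node)."""

    if edge.parent is None:
        raise TreeError("the root has no incoming edge")
    if edge.index >= len(tree.nodes) or tree.nodes[edge.index] is not edge:
        raise TreeError("edge does not belong to this tree")
    return Split.of(tree.leaves_below(edge), tree.leaf_labels)


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------


def _dendropy_to_graph(dtree: "dendropy.Tree"):
    """Convert a dendropy tree to an undirected adjacency structure."""

    ids = {}
    labels = {}
    adj: dict[int, list] = {}

    for node in dtree.preorder_node_iter():
        nid = ids.setdefault(id(node), len(ids))
        adj.setdefault(nid, [])
        label = ""
        if node.taxon is not None and node.taxon.label:
            label = str(node.taxon.label)
        elif node.label:
            label = str(node.label)
        labels[nid] = label
        if node.parent_node is not None:
            pid = ids[id(node.parent_node)]
            length = node.edge.length
            adj[nid].append((pid, length))
            adj[pid].append((nid, length))
    return adj, labels


def _suppress_degree_two(adj: dict, labels: dict) -> None:
    """Remove unlabeled degree-2 vertices, merging their incident edges."""

    for v in list(adj):
        if len(adj[v]) == 2 and not labels.get(v):
            (a, la), (b, lb) = adj[v]
            merged = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
            adj[a] = [(x, l) for (x, l) in adj[a] if x != v] + [(b, merged)]
            adj[b] = [(x, l) for (x, l) in adj[b] if x != v] + [(a, merged)]
            del adj[v]


def _graph_to_rooted(adj: dict, labels: dict, root_label: str) -> RootedTree:
    by_label = {labels[v]: v for v in adj if labels.get(v)}
    if root_label not in by_label:
        raise TreeError(f"no leaf labeled {root_label!r}")
    rid = by_label[root_label]
    if len(adj[rid]) != 1:
        raise TreeError(f"label {root_label!r} is not a leaf")

    nodes: dict[int, TreeNode] = {}

    def _build(v: int, parent: Optional[int], length) -> TreeNode:
        node = TreeNode(labels.get(v, ""), length)
        nodes[v] = node
        nbrs = [(u, l) for (u, l) in adj[v] if u != parent]
        if parent is not None and nbrs and node.label:
            raise TreeError(f"internal node carries leaf label {node.label!r}")
        if parent is not None and len(nbrs) not in (0, 2):
            raise TreeError("non-binary internal node (polytomy)")
        for (u, l) in nbrs:
            node.add_child(_build(u, v, l))
        return node

    root = _build(rid, None, None)
    return RootedTree(root)


def parse_newick(text: str, root_leaf: Optional[str] = None) -> RootedTree:
    """Parse a Newick string into a leaf-rooted binary tree.

    The input may be unrooted (trifurcating base) or rooted at an internal
    node; it is re-rooted at *root_leaf* (default: lexicographically smallest
    leaf label).  Polytomies and duplicate labels are rejected.
    """

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    adj, labels = _dendropy_to_graph(dtree)
    leaf_labels = [labels[v] for v in adj if len(adj[v]) == 1]
    if any(not l for l in leaf_labels):
        raise TreeError("leaf with empty label")
    if len(leaf_labels) != len(set(leaf_labels)):
        raise TreeError("duplicate leaf labels")
    _suppress_degree_two(adj, labels)
    for v in adj:
        if len(adj[v]) not in (1, 3):
            raise TreeError("non-binary internal node (polytomy)")
    if root_leaf is None:
        root_leaf = min(leaf_labels)
    return _graph_to_rooted(adj, labels, root_leaf)


def write_newick(tree: RootedTree, lengths: bool = True) -> str:
    """Serialize a leaf-rooted tree; the root leaf becomes the outermost label."""

    def _fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(_fmt(c) for c in node.children) + ")"
        if lengths and node.length is not None:
            s += f":{node.length:g}"
        return s

    if tree.root.is_leaf:
        return f"{tree.root.label};"
    inner = _fmt(tree.root.children[0])
    return f"({inner}){tree.root.label};"


def root_at_leaf(tree: RootedTree, leaf: Optional[str] = None) -> RootedTree:
    """Re-root *tree* at the given leaf label (default: smallest label).

    The set of splits is unchanged; only the direction of edges (and hence
    preorder indices) changes.
    """

    if leaf is None:
        leaf = min(tree.leaf_labels)
    if tree.root.label == leaf:
        return tree.copy()
    if leaf not in tree.leaf_labels:
        raise TreeError(f"no leaf labeled {leaf!r}")

    # Rebuild as an undirected graph and orient from the new root.
    adj: dict[int, list] = {}
    labels: dict[int, str] = {}
    for node in tree.nodes:
        adj.setdefault(node.index, [])
        labels[node.index] = node.label
        if node.parent is not None:
            adj[node.index].append((node.parent.index, node.length))
            adj[node.parent.index].append((node.index, node.length))
    _suppress_degree_two(adj, labels)
    return _graph_to_rooted(adj, labels, leaf)


# ---------------------------------------------------------------------------
# Random topologies
# ---------------------------------------------------------------------------


class _ShapeNode:
    __slots__ = ("label", "children")

    def __init__(self, label=None):
        self.label = label
        self.children = []


def sample_rooted_shape(labels: Sequence[str], rng: np.random.Generator):
    """Uniform rooted binary topology over the given labels.

    Sampling is by sequential leaf attachment: with ``k`` leaves placed there
    are ``2k - 1`` attachment positions (every edge plus a new root above the
    current one), giving the uniform distribution over the ``(2n-3)!!``
    rooted shapes.  Returns a canonical nested-tuple representation where
    leaves are labels and internal nodes are pairs sorted by smallest
    descendant label.
    """

    labels = list(labels)
    if len(labels) < 1:
        raise TreeError("need at least one label")
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate labels")

    root = _ShapeNode(labels[0])
    # Attachment positions with k leaves placed: every edge (one per non-root
    # node) plus the position above the current root -- picking the current
    # root node stands for the latter, giving 2k-1 uniform choices.
    nodes = [root]
    for lab in labels[1:]:
        target = nodes[int(rng.integers(0, len(nodes)))]
        leaf = _ShapeNode(lab)
        new = _ShapeNode()
        if target is root:
            new.children = [root, leaf]
            root = new
        else:
            parent = _find_parent(root, target)
            new.children = [target, leaf]
            parent.children[parent.children.index(target)] = new
        nodes.append(leaf)
        nodes.append(new)

    def _tupled(node: _ShapeNode):
        if node.label is not None:
            return node.label
        subs = [_tupled(c) for c in node.children]
        subs.sort(key=_min_of)
        return tuple(subs)

    return _tupled(root)


def _find_parent(root: _ShapeNode, target: _ShapeNode):
    stack = [root]
    while stack:
        v = stack.pop()
        for c in v.children:
            if c is target:
                return v
            stack.append(c)
    return None


def _min_of(shape) -> str:
    if isinstance(shape, str):
        return shape
    return min(_min_of(c) for c in shape)


def _shape_to_node(shape) -> TreeNode:
    if isinstance(shape, str):
        return TreeNode(shape)
    node = TreeNode()
    for c in shape:
        node.add_child(_shape_to_node(c))
    return node


def random_topology(
    labels, rng: np.random.Generator, root_leaf: Optional[str] = None
) -> RootedTree:
    """Uniform random binary topology, rooted in a leaf.

    *labels* is a sequence of leaf labels or an integer ``n`` (labels
    ``s01 .. sNN``).  The unrooted shape is uniform over the ``(2n-5)!!``
    unrooted topologies (the root position of the uniformly sampled rooted
    shape is marginalised away by re-rooting); the returned tree is rooted at
    *root_leaf* (default: smallest label).
    """

    if isinstance(labels, (int, np.integer)):
        n = int(labels)
        if n < 2:
            raise TreeError("need at least two leaves")
        width = max(2, len(str(n)))
        labels = [f"s{i:0{width}d}" for i in range(1, n + 1)]
    labels = list(labels)
    if len(labels) < 2:
        raise TreeError("need at least two leaves")
    shape = sample_rooted_shape(labels, rng)
    if isinstance(shape, str):  # single leaf; cannot happen for n >= 2
        raise TreeError("degenerate topology")

    # Build an internally-rooted tree, then re-root at a leaf.
    top = _shape_to_node(shape)
    tree = RootedTree(top, validate=False)
    return root_at_leaf(tree, root_leaf)
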