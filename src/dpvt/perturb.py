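"""Tree perturbations that introduce non-MP edges into MP trees.

Two operators are provided.  A rooted SPR move prunes a subtree and
regrafts it onto another edge, uniformly over all (prune, regraft) pairs
that change the topology.  A random bounded-depth subtree replacement
deletes the depth-d subgraph below a random eligible node and reattaches
its frontier subtrees, in random order, as the leaves of a fresh uniformly
random rooted binary shape.  Both preserve the leaf set and the binary,
rooted-in-a-leaf shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .parsimony import EdgeLabels, label_edges
from .trees import RootedTree, TreeError, TreeNode, sample_rooted_shape

__all__ = [
    "PerturbationSpec",
    "PerturbationError",
    "spr_move",
    "apply_spr_perturbation",
    "all_spr_neighbors",
    "bounded_depth_subtree_replacement",
    "perturb_until_fraction",
    "default_spr_count",
]


class PerturbationError(RuntimeError):
    """A perturbation could not be performed or a retry budget ran out."""


@dataclass
class PerturbationSpec:
    """How to introduce non-MP edges.

    kind : {"spr", "bounded_subtree", "union"}
        "union" mixes both operators (chosen at random per application).
    spr_count : int or None
        SPR moves per application; default max(1, floor(n/10)).
    depth : int or None
        Bounded-subtree depth; default floor(depth_fraction * tree depth),
        minimum 1.
    depth_fraction : float
        Fraction of total tree depth used when *depth* is None.
    target_fraction : float
        Minimum fraction of non-MP internal edges demanded by
        :func:`perturb_until_fraction`.
    max_attempts : int
        Retry budget before :class:`PerturbationError`.
    """

    kind: str = "spr"
    spr_count: Optional[int] = None
    depth: Optional[int] = None
    depth_fraction: float = 0.5
    target_fraction: float = 1.0 / 3.0
    max_attempts: int = 100

    def __post_init__(self):
        if self.kind not in ("spr", "bounded_subtree", "union"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not (0.0 < self.target_fraction <= 1.0):
            raise ValueError("target_fraction must be in (0, 1]")


def default_spr_count(n_leaves: int) -> int:
    """floor(n/10) SPR moves, clamped to a minimum of one."""

    return max(1, n_leaves // 10)


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------


def _clone(tree: RootedTree) -> Tuple[TreeNode, List[TreeNode]]:
    nodes: List[TreeNode] = []

    def _rec(node: TreeNode) -> TreeNode:
        new = TreeNode(node.label, node.length)
        nodes.append(new)
        for c in node.children:
            new.add_child(_rec(c))
        return new

    root = _rec(tree.root)
    return root, nodes


def _subtree_set(node: TreeNode) -> set:
    out = set()
    stack = [node]
    while stack:
        v = stack.pop()
        out.add(id(v))
        stack.extend(v.children)
    return out


def _spr_pairs(root: TreeNode, nodes: List[TreeNode]):
    """All (prune node, regraft node) pairs yielding a different topology.

    Regraft targets identify the edge above them; the sibling of the pruned
    node is excluded because regrafting onto the merged edge restores the
    original topology.
    """

    pairs = []
    for p in nodes:
        if p.parent is None or p.parent.parent is None:
            continue  # cannot prune the root or the whole tree below it
        u = p.parent
        sib = u.children[0] if u.children[1] is p else u.children[1]
        inside = _subtree_set(p)
        for t in nodes:
            if t.parent is None or t is u or t is sib or id(t) in inside:
                continue
            pairs.append((p, t))
    return pairs


def _apply_spr(root: TreeNode, p: TreeNode, t: TreeNode) -> TreeNode:
    u = p.parent
    g = u.parent
    sib = u.children[0] if u.children[1] is p else u.children[1]
    # Detach p, suppressing its parent u.
    g.children[g.children.index(u)] = sib
    sib.parent = g
    if sib.length is not None and u.length is not None:
        sib.length = sib.length + u.length
    # Regraft onto the edge above t.
    w = TreeNode()
    pt = t.parent
    pt.children[pt.children.index(t)] = w
    w.parent = pt
    w.children = [t, p]
    t.parent = w
    p.parent = w
    w.length = t.length
    return root


def spr_move(tree: RootedTree, rng: np.random.Generator) -> RootedTree:
    """One uniform rooted SPR move; always changes the topology."""

    if tree.n_leaves < 4:
        raise PerturbationError("SPR needs at least four leaves")
    root, nodes = _clone(tree)
    pairs = _spr_pairs(root, nodes)
    if not pairs:
        raise PerturbationError("no valid SPR move exists")
    p, t = pairs[int(rng.integers(0, len(pairs)))]
    return RootedTree(_apply_spr(root, p, t))


def all_spr_neighbors(tree: RootedTree) -> Iterator[RootedTree]:
    """All SPR neighbors of *tree* (with repeats across (prune, regraft) pairs)."""

    if tree.n_leaves < 4:
        return
    root0, nodes0 = _clone(tree)
    pos = {id(n): i for i, n in enumerate(nodes0)}
    index_pairs = [(pos[id(p)], pos[id(t)]) for p, t in _spr_pairs(root0, nodes0)]
    for i, j in index_pairs:
        root, nodes = _clone(tree)  # clone order matches nodes0
        yield RootedTree(_apply_spr(root, nodes[i], nodes[j]))


def apply_spr_perturbation(
    tree: RootedTree, k: int, rng: np.random.Generator
) -> RootedTree:
    """Apply *k* sequential independent SPR moves."""

    if k < 1:
        raise ValueError("k must be >= 1")
    out = tree
    for _ in range(k):
        out = spr_move(out, rng)
    return out


# ---------------------------------------------------------------------------
# Bounded-depth subtree replacement
# ---------------------------------------------------------------------------


def _height(node: TreeNode) -> int:
    best = 0
    stack = [(node, 0)]
    while stack:
        v, d = stack.pop()
        if not v.children:
            best = max(best, d)
        for c in v.children:
            stack.append((c, d + 1))
    return best


def bounded_depth_subtree_replacement(
    tree: RootedTree, d: int, rng: np.random.Generator
) -> RootedTree:
    """Replace the depth-*d* subgraph below a random eligible node.

    A node is eligible if it is internal (not the leaf root) and some leaf
    lies at least *d* edges below it.  The subgraph of nodes within *d*
    edges below the chosen node v is deleted; its frontier (nodes exactly
    *d* edges below v, plus leaves closer than that) is reattached, in
    random order, as the leaf slots of a uniformly random rooted binary
    shape whose root is v.
    """

    if d < 1:
        raise ValueError("depth must be >= 1")
    root, nodes = _clone(tree)
    eligible = [
        v for v in nodes if v.children and v.parent is not None and _height(v) >= d
    ]
    if not eligible:
        raise PerturbationError(f"no internal node has height >= {d}")
    v = eligible[int(rng.integers(0, len(eligible)))]

    # Frontier: roots of the subtrees that survive the deletion.
    frontier: List[TreeNode] = []
    stack = [(c, 1) for c in v.children]
    while stack:
        w, dist = stack.pop()
        if dist == d or not w.children:
            frontier.append(w)
        else:
            stack.extend((c, dist + 1) for c in w.children)

    x = len(frontier)
    if x < 2:  # pragma: no cover - impossible for binary trees with height >= d >= 1
        raise PerturbationError("degenerate frontier")
    order = rng.permutation(x)
    shape = sample_rooted_shape([str(i) for i in range(x)], rng)

    def _build(s) -> TreeNode:
        if isinstance(s, str):
            sub = frontier[order[int(s)]]
            sub.length = None
            return sub
        node = TreeNode()
        for c in s:
            node.add_child(_build(c))
        return node

    v.children = []
    new_top = _build(shape)
    for c in new_top.children:
        v.add_child(c)
    return RootedTree(root)


# ---------------------------------------------------------------------------
# Perturb until a target fraction of non-MP edges
# ---------------------------------------------------------------------------


def perturb_until_fraction(
    tree: RootedTree,
    mp_splits,
    spec: PerturbationSpec,
    rng: np.random.Generator,
) -> Tuple[RootedTree, EdgeLabels]:
    """Perturb repeatedly until >= target fraction of internal edges are non-MP.

    The depth of bounded-subtree replacements is fixed from the *input*
    tree's depth.  Raises :class:`PerturbationError` once the retry budget is
    exhausted (e.g. for alignments where every topology is maximally
    parsimonious, so the fraction is unreachable).
    """

    n = tree.n_leaves
    k = spec.spr_count if spec.spr_count is not None else default_spr_count(n)
    d = spec.depth if spec.depth is not None else max(
        1, int(spec.depth_fraction * tree.depth())
    )

    current = tree
    for _ in range(spec.max_attempts):
        kind = spec.kind
        if kind == "union":
            kind = "spr" if rng.integers(0, 2) == 0 else "bounded_subtree"
        if kind == "spr":
            current = apply_spr_perturbation(current, k, rng)
        else:
            current = bounded_depth_subtree_replacement(current, d, rng)
        labels = label_edges(current, mp_splits)
        if labels.fraction_nonmp >= spec.target_fraction:
            return current, labels
    raise PerturbationError(
        f"could not reach a {spec.target_fraction:.0%} non-MP edge fraction "
        f"within {spec.max_attempts} perturbation attempts"
    )
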