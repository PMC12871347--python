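"""Fitch parsimony: scoring, ancestral reconstruction, and MP-tree search.

The parsimony score of a tree is the minimum number of substitutions needed
to fit the alignment onto it, computed per site with the classic two-pass
Fitch set algorithm and summed.  Nucleotide states are held as 4-bit masks
(A=1, C=2, G=4, T=8) so the bottom-up intersection/union pass vectorises
over sites; identical columns are collapsed to weighted patterns when only
the score is needed.

Maximum-parsimony *edge labels* — is the split of an edge present in any
MP tree for the alignment? — come from an exact enumerator over all
(2n-5)!! unrooted topologies at small n, or from a best-effort SPR
hill-climb that collects the plateau of equally parsimonious trees at
larger n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .trees import (
    RootedTree,
    Split,
    TreeError,
    TreeNode,
    internal_edges,
    random_topology,
    split_of_edge,
)

__all__ = [
    "Alignment",
    "MutationHistory",
    "EdgeLabels",
    "CapabilityError",
    "fitch_score",
    "fitch_reconstruct",
    "enumerate_mp_trees",
    "heuristic_mp_search",
    "mp_split_set",
    "label_edges",
]

ALPHABET = "ACGT"
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CHAR = {1: "A", 2: "C", 4: "G", 8: "T"}


class CapabilityError(RuntimeError):
    """An exact computation was requested beyond its feasible problem size."""


@dataclass
class Alignment:
    """A gap-free nucleotide alignment: label -> sequence over {A,C,G,T}."""

    sequences: Dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        if self.n_sites < 1:
            raise ValueError("alignment must have at least one site")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def labels(self) -> frozenset:
        return frozenset(self.sequences)

    def check_alphabet(self) -> None:
        for label, seq in self.sequences.items():
            if set(seq) - set(ALPHABET):
                bad = sorted(set(seq) - set(ALPHABET))
                raise ValueError(f"sequence {label!r} has non-ACGT characters {bad}")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label in self.sequences:
                fh.write(f">{label}\n{self.sequences[label]}\n")

    def masks(self) -> Dict[str, np.ndarray]:
        """Per-sequence 4-bit state masks, one int16 per site."""

        self.check_alphabet()
        out = {}
        for label, seq in self.sequences.items():
            out[label] = np.array([_BIT[c] for c in seq], dtype=np.int16)
        return out


@dataclass
class MutationHistory:
    """A parsimony-optimal assignment of sequences to all tree nodes.

    ``events[i]`` lists the mutations on the edge above node ``i`` as
    ``(site, from_state, to_state)`` read away from the root; they are
    exactly the positions where the parent and child sequences differ, and
    their total count equals the Fitch score of the tree.
    """

    node_sequences: Dict[int, str]
    events: Dict[int, List[Tuple[int, str, str]]]
    n_sites: int

    @property
    def total_events(self) -> int:
        return sum(len(v) for v in self.events.values())


@dataclass
class EdgeLabels:
    """Per-internal-edge 0/1 ground truth (0 = MP edge, 1 = non-MP edge).

    Edges are listed in preorder of their child-side node; pendant edges are
    excluded (their splits are trivial and present in every tree).
    """

    child_indices: np.ndarray
    labels: np.ndarray
    splits: List[Split] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.labels)

    @property
    def fraction_nonmp(self) -> float:
        return float(np.mean(self.labels)) if self.n_edges else 0.0


# ---------------------------------------------------------------------------
# Pattern compression
# ---------------------------------------------------------------------------


class _Patterns:
    """Unique alignment columns with multiplicities, as 4-bit masks."""

    def __init__(self, alignment: Alignment):
        masks = alignment.masks()
        self.labels = list(alignment.sequences)
        mat = np.stack([masks[l] for l in self.labels])  # (n_seq, n_sites)
        uniq, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(np.int64)
        self.by_label = {l: uniq[i] for i, l in enumerate(self.labels)}


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def _score_tree(tree: RootedTree, pats: _Patterns) -> int:
    """Weighted Fitch score of *tree* under compressed site patterns."""

    cand: Dict[int, np.ndarray] = {}
    score = 0
    for node in tree.postorder():
        if node.is_leaf:
            cand[node.index] = pats.by_label[node.label]
        elif node is tree.root:
            inter = cand[node.children[0].index] & pats.by_label[node.label]
            score += int(pats.weights[inter == 0].sum())
        else:
            a = cand[node.children[0].index]
            b = cand[node.children[1].index]
            inter = a & b
            miss = inter == 0
            score += int(pats.weights[miss].sum())
            cand[node.index] = np.where(miss, a | b, inter)
    return score


def fitch_score(tree: RootedTree, alignment: Alignment, per_site: bool = False):
    """Parsimony score ps_A(T) of *tree* for *alignment*.

    The score is additive over sites and invariant to the choice of root
    leaf.  With ``per_site=True`` an array of per-site scores is returned.
    """

    if tree.leaf_labels != alignment.labels:
        raise ValueError("tree leaf labels do not match alignment labels")
    if not per_site:
        return _score_tree(tree, _Patterns(alignment))

    masks = alignment.masks()
    cand: Dict[int, np.ndarray] = {}
    scores = np.zeros(alignment.n_sites, dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            cand[node.index] = masks[node.label]
        elif node is tree.root:
            scores += (cand[node.children[0].index] & masks[node.label]) == 0
        else:
            a = cand[node.children[0].index]
            b = cand[node.children[1].index]
            inter = a & b
            miss = inter == 0
            scores += miss
            cand[node.index] = np.where(miss, a | b, inter)
    return scores


def fitch_reconstruct(tree: RootedTree, alignment: Alignment) -> MutationHistory:
    """A deterministic parsimony-optimal ancestral reconstruction.

    Top-down tie-break: a node takes its parent's state when that state is in
    its Fitch candidate set, otherwise the alphabetically smallest candidate
    (A < C < G < T).  The root node keeps its own leaf sequence, and the
    total number of inferred mutations equals :func:`fitch_score`.
    """

    if tree.leaf_labels != alignment.labels:
        raise ValueError("tree leaf labels do not match alignment labels")
    masks = alignment.masks()
    cand: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            cand[node.index] = masks[node.label]
        elif node is tree.root:
            pass
        else:
            a = cand[node.children[0].index]
            b = cand[node.children[1].index]
            inter = a & b
            cand[node.index] = np.where(inter == 0, a | b, inter)

    states: Dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            states[node.index] = masks[node.label]
        elif node.is_leaf:
            states[node.index] = masks[node.label]
        else:
            p = states[node.parent.index]
            c = cand[node.index]
            keep = (p & c) != 0
            low = c & (-c)  # lowest set bit: alphabetically smallest candidate
            states[node.index] = np.where(keep, p, low)

    node_sequences = {
        i: "".join(_CHAR[int(b)] for b in arr) for i, arr in states.items()
    }
    events: Dict[int, List[Tuple[int, str, str]]] = {}
    for node in tree.nodes:
        if node.parent is None:
            continue
        pseq = node_sequences[node.parent.index]
        cseq = node_sequences[node.index]
        events[node.index] = [
            (k, pseq[k], cseq[k]) for k in range(len(cseq)) if pseq[k] != cseq[k]
        ]
    return MutationHistory(node_sequences, events, alignment.n_sites)


# ---------------------------------------------------------------------------
# Exact MP-tree enumeration
# ---------------------------------------------------------------------------


def _enumerate_shapes(labels: Sequence[str]) -> Iterator:
    """All rooted binary shapes over *labels*, as nested tuples.

    There are (2k-3)!! of them for k labels; combined with a fixed root
    leaf this enumerates each unrooted topology on k+1 taxa exactly once.
    """

    def _insert(shape, leaf):
        yield (shape, leaf)  # above the current (sub)root
        if isinstance(shape, tuple):
            a, b = shape
            for a2 in _insert(a, leaf):
                yield (a2, b)
            for b2 in _insert(b, leaf):
                yield (a, b2)

    def _rec(k: int):
        if k == 1:
            yield labels[0]
            return
        for smaller in _rec(k - 1):
            yield from _insert(smaller, labels[k - 1])

    yield from _rec(len(labels))


def _shape_score(shape, root_mask: np.ndarray, pats: _Patterns) -> int:
    weights = pats.weights

    def _rec(s):
        if isinstance(s, str):
            return pats.by_label[s], 0
        (a_mask, a_sc) = _rec(s[0])
        (b_mask, b_sc) = _rec(s[1])
        inter = a_mask & b_mask
        miss = inter == 0
        sc = a_sc + b_sc + int(weights[miss].sum())
        return np.where(miss, a_mask | b_mask, inter), sc

    mask, sc = _rec(shape)
    sc += int(weights[(mask & root_mask) == 0].sum())
    return sc


def _shape_to_tree(root_label: str, shape) -> RootedTree:
    def _build(s) -> TreeNode:
        if isinstance(s, str):
            return TreeNode(s)
        node = TreeNode()
        node.add_child(_build(s[0]))
        node.add_child(_build(s[1]))
        return node

    root = TreeNode(root_label)
    root.add_child(_build(shape))
    return RootedTree(root)


def enumerate_mp_trees(alignment: Alignment, max_n: int = 10) -> List[RootedTree]:
    """Exactly the set of maximum-parsimony topologies for *alignment*.

    All (2n-5)!! unrooted topologies are scored; the returned trees (rooted
    at the smallest leaf label) are those achieving the minimum score.
    Beyond *max_n* sequences the enumeration is refused; use
    :func:`heuristic_mp_search` instead.
    """

    labels = sorted(alignment.sequences)
    n = len(labels)
    if n > max_n:
        raise CapabilityError(
            f"exact MP enumeration over (2n-5)!! topologies is limited to "
            f"n <= {max_n} (got n = {n}); use heuristic_mp_search for larger trees"
        )
    if n < 3:
        raise ValueError("need at least three sequences")
    pats = _Patterns(alignment)
    root_label = labels[0]
    root_mask = pats.by_label[root_label]

    best = None
    best_shapes: list = []
    for shape in _enumerate_shapes(labels[1:]):
        sc = _shape_score(shape, root_mask, pats)
        if best is None or sc < best:
            best = sc
            best_shapes = [shape]
        elif sc == best:
            best_shapes.append(shape)
    return [_shape_to_tree(root_label, s) for s in best_shapes]


# ---------------------------------------------------------------------------
# Heuristic MP-plateau search (best-effort stand-in at larger n)
# ---------------------------------------------------------------------------


def heuristic_mp_search(
    alignment: Alignment,
    rng: np.random.Generator,
    n_starts: int = 2,
    max_trees: int = 200,
    max_expansions: int = 30,
) -> List[RootedTree]:
    """SPR hill-climbing search collecting a plateau of equally-best trees.

    From each random start the search moves greedily to the best-scoring SPR
    neighbor until no improvement exists, then breadth-first explores
    equal-score neighbors of the best trees found (up to *max_expansions*
    neighborhood expansions, at most *max_trees* topologies).  Labels derived
    from this search mean "in the discovered MP plateau", not a certificate
    of global optimality.
    """

    from .perturb import all_spr_neighbors

    labels = sorted(alignment.sequences)
    if alignment.labels != frozenset(labels):  # pragma: no cover - tautology guard
        raise ValueError("inconsistent labels")
    pats = _Patterns(alignment)

    best_score = None
    best_trees: Dict[frozenset, RootedTree] = {}

    def _consider(tree: RootedTree, score: int):
        nonlocal best_score, best_trees
        if best_score is None or score < best_score:
            best_score = score
            best_trees = {}
        if score == best_score and len(best_trees) < max_trees:
            key = tree.internal_splits()
            best_trees.setdefault(key, tree)

    for _ in range(n_starts):
        tree = random_topology(labels, rng)
        score = _score_tree(tree, pats)
        improved = True
        while improved:
            improved = False
            best_nbr, best_nbr_score = None, score
            for nbr in all_spr_neighbors(tree):
                s = _score_tree(nbr, pats)
                if s < best_nbr_score:
                    best_nbr, best_nbr_score = nbr, s
            if best_nbr is not None:
                tree, score = best_nbr, best_nbr_score
                improved = True
        _consider(tree, score)

    # Plateau exploration around the local optima.
    frontier = list(best_trees.values())
    seen = set(best_trees)
    expansions = 0
    while frontier and expansions < max_expansions and len(best_trees) < max_trees:
        tree = frontier.pop(0)
        expansions += 1
        for nbr in all_spr_neighbors(tree):
            s = _score_tree(nbr, pats)
            if s > best_score:
                continue
            if s < best_score:  # plateau search found an improvement; restart frontier
                _consider(nbr, s)
                frontier = list(best_trees.values())
                seen = set(best_trees)
                break
            key = nbr.internal_splits()
            if key not in seen:
                seen.add(key)
                _consider(nbr, s)
                frontier.append(nbr)
    return list(best_trees.values())


# ---------------------------------------------------------------------------
# Edge labels
# ---------------------------------------------------------------------------


def mp_split_set(mp_trees: Iterable[RootedTree]) -> frozenset:
    """Union of internal splits over a collection of MP topologies."""

    trees = list(mp_trees)
    if not trees:
        raise ValueError("empty tree collection")
    out: set = set()
    for t in trees:
        out |= t.internal_splits()
    return frozenset(out)


def label_edges(tree: RootedTree, mp_splits: Iterable[Split]) -> EdgeLabels:
    """Label each internal edge 0 (split in an MP tree) or 1 (non-MP edge)."""

    mp_splits = frozenset(mp_splits)
    if not mp_splits:
        raise ValueError("empty MP split set (no MP trees provided)")
    universe = next(iter(mp_splits))
    if universe.side_a | universe.side_b != tree.leaf_labels:
        raise ValueError("MP splits are over a different leaf set than the tree")
    idx, lab, splits = [], [], []
    for v in internal_edges(tree, "preorder"):
        s = split_of_edge(tree, v)
        idx.append(v.index)
        lab.append(0 if s in mp_splits else 1)
        splits.append(s)
    return EdgeLabels(
        np.array(idx, dtype=np.int64), np.array(lab, dtype=np.int8), splits
    )
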