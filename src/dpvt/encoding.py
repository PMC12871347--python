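"""Tensor encodings of trees and mutation histories.

Two fixed tensors drive the network.  The *traversal tensor* (2 x (n-3) x 3)
lists, for each internal edge, the node-index triple consumed by the
recurrent unit: slice 0 visits edges bottom-up (postorder) with the edge's
lower node v and its two children x, y; slice 1 visits them top-down
(preorder) with the edge's upper node v, v's parent x, and the sibling
edge's child node y.  Because both slices cover the same n-3 edges and the
top-down visit order is by ascending lower-node index, the lower node of
the k-th top-down visit is recoverable from slice 0 alone, keeping the
tensor self-contained.

The *mutation tensor* ((n-3) x N x 4) encodes the inferred mutation per
internal edge and site over channels [mu_A, mu_G, mu_C, mu_T]: -1 at the
lost state, +1 at the gained state (read away from the root), all-zero when
the site does not mutate on that edge.  NOTE the channel order A, G, C, T —
as fixed by the encoding convention, not alphabetical.  Pendant edges have
no rows here; their encodings (needed as recurrent-unit inputs) are carried
in a per-node auxiliary array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .parsimony import MutationHistory
from .trees import RootedTree, internal_edges

__all__ = [
    "CHANNELS",
    "MutationTensor",
    "TraversalTensor",
    "EncodedExample",
    "BatchedExample",
    "encode_event",
    "encode_mutations",
    "encode_all_edges",
    "build_traversals",
    "batch_examples",
]

#: Channel order of mutation encodings: [mu_A, mu_G, mu_C, mu_T].
CHANNELS = "AGCT"
_CH = {c: i for i, c in enumerate(CHANNELS)}


def encode_event(from_state: str, to_state: str) -> np.ndarray:
    """4-vector for a single mutation; antisymmetric under direction reversal."""

    if from_state == to_state:
        raise ValueError("mutation with identical from/to state")
    vec = np.zeros(4, dtype=np.int8)
    vec[_CH[from_state]] = -1
    vec[_CH[to_state]] = 1
    return vec


@dataclass
class MutationTensor:
    """(n-3) x N x 4 mutation encodings for the internal edges.

    Rows are ordered by the edge's child-node preorder index, recorded in
    ``child_indices``.
    """

    entries: np.ndarray
    child_indices: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sites(self) -> int:
        return self.entries.shape[1]


@dataclass
class TraversalTensor:
    """2 x (n-3) x 3 node-index triples driving the two traversal passes."""

    entries: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.entries.shape[1]

    @property
    def bottom_up(self) -> np.ndarray:
        return self.entries[0]

    @property
    def top_down(self) -> np.ndarray:
        return self.entries[1]


def encode_mutations(history: MutationHistory, tree: RootedTree) -> MutationTensor:
    """Mutation tensor for the internal edges of *tree* under *history*."""

    edges = internal_edges(tree, "preorder")
    n_sites = history.n_sites
    entries = np.zeros((len(edges), n_sites, 4), dtype=np.int8)
    child_indices = np.array([v.index for v in edges], dtype=np.int64)
    for row, v in enumerate(edges):
        for (site, a, b) in history.events.get(v.index, []):
            entries[row, site] = encode_event(a, b)
    return MutationTensor(entries, child_indices)


def encode_all_edges(history: MutationHistory, tree: RootedTree) -> np.ndarray:
    """Per-node mutation encodings, pendant edges included.

    Shape (num_nodes, N, 4); row i encodes the edge above node i (the root's
    row stays zero).  Internal-edge rows agree with
    :func:`encode_mutations`.
    """

    full = np.zeros((len(tree.nodes), history.n_sites, 4), dtype=np.int8)
    for node in tree.nodes:
        if node.parent is None:
            continue
        for (site, a, b) in history.events.get(node.index, []):
            full[node.index, site] = encode_event(a, b)
    return full


def build_traversals(tree: RootedTree) -> TraversalTensor:
    """Traversal tensor of *tree* (empty, shape 2x0x3, below four leaves)."""

    post = internal_edges(tree, "postorder")
    pre = internal_edges(tree, "preorder")
    entries = np.zeros((2, len(post), 3), dtype=np.int64)
    for k, v in enumerate(post):
        x, y = v.children
        entries[0, k] = (x.index, y.index, v.index)
    for k, w in enumerate(pre):
        v = w.parent
        x = v.parent
        y = v.children[0] if v.children[1] is w else v.children[1]
        entries[1, k] = (x.index, y.index, v.index)
    return TraversalTensor(entries)


# ---------------------------------------------------------------------------
# Examples and batching
# ---------------------------------------------------------------------------


@dataclass
class EncodedExample:
    """One labeled, tensor-encoded candidate tree."""

    newick: str
    traversals: TraversalTensor
    mutations: MutationTensor
    full_mutations: np.ndarray  # (num_nodes, N, 4), pendant edges included
    labels: np.ndarray  # (n-3,) int8, aligned with mutations.child_indices
    node_sequences: Dict[int, str] = field(default_factory=dict)
    meta: Dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.mutations.n_edges

    @property
    def n_sites(self) -> int:
        return self.mutations.n_sites


@dataclass
class BatchedExample:
    """A rectangular batch with padding masks.

    The site axis is padded with zero vectors to a common width and flagged
    in ``site_mask``; the edge axis is padded across trees of different
    sizes and flagged in ``edge_mask``.  Masked positions contribute nothing
    to pooling or loss.
    """

    traversals: List[np.ndarray]  # per example, (2, E_i, 3)
    mutations: np.ndarray  # (B, E_max, N_max, 4)
    full_mutations: List[np.ndarray]  # per example, (V_i, N_max, 4)
    labels: np.ndarray  # (B, E_max) float64
    site_mask: np.ndarray  # (B, N_max) bool
    edge_mask: np.ndarray  # (B, E_max) bool

    @property
    def n_examples(self) -> int:
        return len(self.traversals)


def batch_examples(
    examples: Sequence[EncodedExample], target_sites: Optional[int] = None
) -> BatchedExample:
    """Pad a list of encoded examples into one rectangular batch."""

    examples = list(examples)
    if not examples:
        raise ValueError("empty batch")
    n_max = max(e.n_sites for e in examples)
    if target_sites is None:
        target_sites = n_max
    if n_max > target_sites:
        raise ValueError(
            f"example with {n_max} sites exceeds target width {target_sites}"
        )
    e_max = max(e.n_edges for e in examples)
    b = len(examples)

    mutations = np.zeros((b, e_max, target_sites, 4), dtype=np.int8)
    labels = np.zeros((b, e_max), dtype=np.float64)
    site_mask = np.zeros((b, target_sites), dtype=bool)
    edge_mask = np.zeros((b, e_max), dtype=bool)
    traversals = []
    fulls = []
    for i, ex in enumerate(examples):
        ne, ns = ex.n_edges, ex.n_sites
        mutations[i, :ne, :ns] = ex.mutations.entries
        labels[i, :ne] = ex.labels
        site_mask[i, :ns] = True
        edge_mask[i, :ne] = True
        traversals.append(ex.traversals.entries)
        full = np.zeros((ex.full_mutations.shape[0], target_sites, 4), dtype=np.int8)
        full[:, :ns] = ex.full_mutations
        fulls.append(full)
    return BatchedExample(traversals, mutations, fulls, labels, site_mask, edge_mask)
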