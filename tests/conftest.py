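"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dpvt import Alignment, RootedTree, parse_newick, random_topology


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def quartet():
    """The smallest informative case: four leaves, one internal edge."""

    return parse_newick("((A,B),(C,D));")


def random_alignment(labels, n_sites, rng) -> Alignment:
    """Uniform i.i.d. nucleotide alignment (no phylogenetic signal)."""

    chars = np.array(list("ACGT"))
    return Alignment(
        {l: "".join(rng.choice(chars, size=n_sites)) for l in sorted(labels)}
    )


def brute_force_parsimony(tree: RootedTree, alignment: Alignment) -> int:
    """Exhaustive minimisation over all internal-node state assignments.

    The oracle for the Fitch score: for every site, try every assignment of
    {A,C,G,T} to every internal node and count mismatched edges, keeping the
    minimum.  Exponential in the number of internal nodes; for n <= 6 leaves
    there are at most 4^4 assignments.
    """

    internal = [v for v in tree.nodes if v.children and v is not tree.root]
    leaves = {v.index: alignment.sequences[v.label] for v in tree.leaves}
    total = 0
    for site in range(alignment.n_sites):
        best = None
        for combo in itertools.product("ACGT", repeat=len(internal)):
            states = {v.index: combo[i] for i, v in enumerate(internal)}
            states.update({i: seq[site] for i, seq in leaves.items()})
            changes = sum(
                1
                for v in tree.nodes
                if v.parent is not None and states[v.index] != states[v.parent.index]
            )
            best = changes if best is None else min(best, changes)
        total += best
    return total


def pairwise_auroc(scores, labels) -> float:
    """Brute-force AUROC over all (positive, negative) pairs; ties count 1/2."""

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def enumerate_topologies(labels):
    """Independent enumerator of all unrooted topologies over *labels*.

    Builds trees by inserting each leaf onto every edge of every smaller
    tree, working on Newick strings rooted at the first label, and yields
    each topology as a RootedTree.  Used to cross-check the package's
    internal enumeration.
    """

    labels = sorted(labels)

    def _insert(shape, leaf):
        if isinstance(shape, str):
            yield (shape, leaf)
            return
        yield (shape, leaf)
        a, b = shape
        for a2 in _insert(a, leaf):
            yield (a2, b)
        for b2 in _insert(b, leaf):
            yield (a, b2)

    shapes = [labels[1]]
    for lab in labels[2:]:
        shapes = [s2 for s in shapes for s2 in _insert(s, lab)]

    def _newick(s):
        if isinstance(s, str):
            return s
        return "(" + _newick(s[0]) + "," + _newick(s[1]) + ")"

    for s in shapes:
        yield parse_newick(f"({_newick(s)}){labels[0]};", root_leaf=labels[0])
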