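"""Jukes–Cantor simulation, alignment filtering, and labeled-dataset assembly.

Alignments are simulated under the Jukes–Cantor model: a uniform root
sequence evolves independently at each site down a random topology with
i.i.d. exponential branch lengths, a site changing state along a branch of
length t (expected substitutions per site) with probability
``3/4 * (1 - exp(-4t/3))`` and landing uniformly on the other three states.

Filtering removes sites with gaps or ambiguous characters, sites that are
uninformative for parsimony (constant, or with a single deviating
sequence), and duplicate sequences; simulation oversizes by twice the
target length and five extra sequences so the target dimensions survive
filtering, retrying when they do not.

Dataset assembly chains the full pipeline: alignment -> MP-tree collection
(exact enumeration at small n, SPR-plateau search beyond) -> topology
subsample -> perturbation -> Fitch reconstruction -> tensor encoding ->
exact 0/1 edge labels against the MP split set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .encoding import EncodedExample, build_traversals, encode_all_edges, encode_mutations
from .parsimony import (
    Alignment,
    CapabilityError,
    enumerate_mp_trees,
    fitch_reconstruct,
    heuristic_mp_search,
    label_edges,
    mp_split_set,
)
from .perturb import PerturbationSpec, apply_spr_perturbation, default_spr_count, perturb_until_fraction
from .trees import RootedTree, random_topology, write_newick

__all__ = [
    "SimulationSpec",
    "FilterError",
    "DEFAULT_BRANCH_LENGTH_MEAN",
    "random_jc_tree",
    "simulate_jc_alignment",
    "filter_alignment",
    "oversimulate_and_trim",
    "build_example",
    "generate_labeled_dataset",
]

_STATES = "ACGT"

#: Default mean of the exponential branch-length prior (expected
#: substitutions per site), chosen so that a 2x-length simulation reliably
#: survives parsimony-informativeness filtering at the target dimensions.
DEFAULT_BRANCH_LENGTH_MEAN = 0.15


class FilterError(ValueError):
    """Filtering removed everything (or below the required dimensions)."""


@dataclass
class SimulationSpec:
    """Target dimensions and priors for one simulated alignment.

    Simulation oversizes to ``2 * n_sites`` sites and ``n_sequences + 5``
    sequences before filtering, then trims back to the target.
    """

    n_sequences: int
    n_sites: int
    branch_length_mean: float = DEFAULT_BRANCH_LENGTH_MEAN
    max_retries: int = 20

    def __post_init__(self):
        if self.n_sequences < 4:
            raise ValueError("need at least four sequences")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.branch_length_mean <= 0:
            raise ValueError("branch_length_mean must be positive")


def random_jc_tree(
    labels, rng: np.random.Generator, branch_length_mean: float = DEFAULT_BRANCH_LENGTH_MEAN
) -> RootedTree:
    """Uniform random leaf-rooted topology with i.i.d. exponential branch lengths."""

    tree = random_topology(labels, rng)
    for node in tree.nodes:
        if node.parent is not None:
            node.length = float(rng.exponential(branch_length_mean))
    return tree


def simulate_jc_alignment(
    tree: RootedTree,
    n_sites: int,
    rng: np.random.Generator,
    return_node_sequences: bool = False,
):
    """Simulate sequences down *tree* under Jukes–Cantor.

    Branch lengths are expected substitutions per site and must be
    non-negative (zero-length branches copy the parent state).  Returns an
    :class:`Alignment` over the leaf labels; with
    ``return_node_sequences=True`` also the true sequences of every node.
    """

    states: Dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[node.index] = rng.integers(0, 4, size=n_sites)
            continue
        t = node.length
        if t is None or t < 0:
            raise ValueError(
                f"node {node.index} has missing or negative branch length"
            )
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        parent = states[node.parent.index]
        change = rng.random(n_sites) < p_change
        jump = rng.integers(1, 4, size=n_sites)
        states[node.index] = np.where(change, (parent + jump) % 4, parent)

    def _decode(arr: np.ndarray) -> str:
        return "".join(_STATES[i] for i in arr)

    seqs = {leaf.label: _decode(states[leaf.index]) for leaf in tree.leaves}
    aln = Alignment(seqs)
    if return_node_sequences:
        return aln, {i: _decode(a) for i, a in states.items()}
    return aln


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _informative_site(column: str) -> bool:
    """Keep a site unless constant or with exactly one deviating sequence."""

    counts: Dict[str, int] = {}
    for c in column:
        counts[c] = counts.get(c, 0) + 1
    return max(counts.values()) < len(column) - 1


def _filter_sites(sequences: Dict[str, str]) -> Dict[str, str]:
    labels = list(sequences)
    n_sites = len(next(iter(sequences.values())))
    keep = []
    for k in range(n_sites):
        col = "".join(sequences[l][k] for l in labels)
        if any(c not in _STATES for c in col):
            continue
        if not _informative_site(col):
            continue
        keep.append(k)
    return {l: "".join(sequences[l][k] for k in keep) for l in labels}


def _drop_duplicates(sequences: Dict[str, str]) -> Dict[str, str]:
    seen: Dict[str, str] = {}
    for label in sorted(sequences):
        seq = sequences[label]
        if seq not in seen:
            seen[seq] = label
    kept = set(seen.values())
    return {l: s for l, s in sequences.items() if l in kept}


def filter_alignment(alignment) -> Alignment:
    """Apply the parsimony pre-processing filters.

    Each pass removes, in order: sites with gaps or ambiguous characters,
    parsimony-uninformative sites (constant, or with only one sequence
    deviating from all others), then duplicate sequences.  Dropping
    duplicates can render further sites uninformative, so the pass repeats
    until a fixpoint, making the filter idempotent.
    """

    seqs = dict(alignment.sequences if isinstance(alignment, Alignment) else alignment)
    seqs = {l: s.upper() for l, s in seqs.items()}
    while True:
        before = (len(seqs), len(next(iter(seqs.values()))) if seqs else 0)
        seqs = _filter_sites(seqs)
        if not seqs or len(next(iter(seqs.values()))) == 0:
            raise FilterError("all sites removed by filtering")
        seqs = _drop_duplicates(seqs)
        if len(seqs) < 2:
            raise FilterError("fewer than two sequences left after filtering")
        after = (len(seqs), len(next(iter(seqs.values()))))
        if after == before:
            return Alignment(seqs)


def oversimulate_and_trim(
    spec: SimulationSpec, rng: np.random.Generator
) -> Alignment:
    """Simulate, filter, and trim to exactly the target dimensions.

    Each attempt simulates ``2 * n_sites`` sites on ``n_sequences + 5``
    leaves, filters, keeps the first ``n_sequences`` labels, re-filters the
    sites, and trims to ``n_sites``; it retries (up to ``max_retries``) when
    the filtered alignment falls short of the target.
    """

    n_sim = spec.n_sequences + 5
    width = max(2, len(str(n_sim)))
    labels = [f"s{i:0{width}d}" for i in range(1, n_sim + 1)]
    for _ in range(spec.max_retries):
        tree = random_jc_tree(labels, rng, spec.branch_length_mean)
        raw = simulate_jc_alignment(tree, 2 * spec.n_sites, rng)
        try:
            filtered = filter_alignment(raw)
        except FilterError:
            continue
        if filtered.n_sequences < spec.n_sequences:
            continue
        kept = sorted(filtered.sequences)[: spec.n_sequences]
        sub = {l: filtered.sequences[l] for l in kept}
        sub = _filter_sites(sub)
        if not sub or len(next(iter(sub.values()))) < spec.n_sites:
            continue
        trimmed = {l: s[: spec.n_sites] for l, s in sub.items()}
        return Alignment(trimmed)
    raise FilterError(
        f"could not reach {spec.n_sequences} x {spec.n_sites} after "
        f"{spec.max_retries} attempts; increase branch_length_mean or the "
        f"simulated length"
    )


# ---------------------------------------------------------------------------
# Labeled examples
# ---------------------------------------------------------------------------


def build_example(
    tree: RootedTree,
    alignment: Alignment,
    mp_splits,
    meta: Optional[Dict] = None,
) -> EncodedExample:
    """Fitch-reconstruct, encode, and label one candidate tree.

    The mutation encodings come from the Fitch reconstruction (the pipeline
    has no other ancestral sequences), and the labels compare each internal
    edge's split against the MP split set.
    """

    history = fitch_reconstruct(tree, alignment)
    labels = label_edges(tree, mp_splits)
    meta = dict(meta or {})
    meta.setdefault("root_label", tree.root.label)
    meta.setdefault("n_leaves", tree.n_leaves)
    meta.setdefault("n_sites", alignment.n_sites)
    return EncodedExample(
        newick=write_newick(tree, lengths=False),
        traversals=build_traversals(tree),
        mutations=encode_mutations(history, tree),
        full_mutations=encode_all_edges(history, tree),
        labels=labels.labels.astype(np.int8),
        node_sequences=dict(history.node_sequences),
        meta=meta,
    )


def generate_labeled_dataset(
    spec: SimulationSpec,
    count: int,
    perturbation: PerturbationSpec,
    rng: np.random.Generator,
    max_trees: int = 200,
    labeling: str = "exact",
    max_exact_n: int = 10,
) -> List[EncodedExample]:
    """End-to-end labeled dataset from *count* simulated alignments.

    ``labeling="exact"`` demands exhaustive MP enumeration (refused above
    *max_exact_n* sequences before any compute); ``labeling="heuristic"``
    uses the SPR-plateau search, so labels mean "in the discovered MP
    plateau".  At most *max_trees* MP topologies per alignment are kept
    (uniform subsample without replacement).
    """

    if labeling not in ("exact", "heuristic"):
        raise ValueError(f"unknown labeling mode {labeling!r}")
    if labeling == "exact" and spec.n_sequences > max_exact_n:
        raise CapabilityError(
            f"exact labeling requires n <= {max_exact_n} sequences "
            f"(got {spec.n_sequences}); use labeling='heuristic'"
        )

    out: List[EncodedExample] = []
    for a in range(count):
        alignment = oversimulate_and_trim(spec, rng)
        if labeling == "exact":
            mp_trees = enumerate_mp_trees(alignment, max_n=max_exact_n)
        else:
            # collect the plateau up to the standard 200-topology cap: the
            # MP split set must come from the full discovered plateau even
            # when far fewer trees are sampled for perturbation
            mp_trees = heuristic_mp_search(
                alignment, rng, max_trees=max(200, max_trees)
            )
        splits = mp_split_set(mp_trees)
        if len(mp_trees) > max_trees:
            idx = rng.choice(len(mp_trees), size=max_trees, replace=False)
            mp_trees = [mp_trees[i] for i in sorted(idx)]
        for t_i, mp_tree in enumerate(mp_trees):
            if perturbation.kind == "spr":
                # The SPR recipe applies a fixed floor(n/10) moves (minimum
                # one); only the subtree-replacement recipes loop until the
                # target non-MP fraction is reached.
                k = (
                    perturbation.spr_count
                    if perturbation.spr_count is not None
                    else default_spr_count(mp_tree.n_leaves)
                )
                perturbed = apply_spr_perturbation(mp_tree, k, rng)
            else:
                perturbed, _ = perturb_until_fraction(mp_tree, splits, perturbation, rng)
            meta = {
                "alignment_id": a,
                "tree_id": t_i,
                "perturbation": perturbation.kind,
                "labeling": labeling,
            }
            out.append(build_example(perturbed, alignment, splits, meta))
    return out
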