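"""Jukes-Cantor simulation, filtering, and labeled-dataset assembly."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpvt import (
    Alignment,
    PerturbationSpec,
    SimulationSpec,
    enumerate_mp_trees,
    filter_alignment,
    generate_labeled_dataset,
    label_edges,
    mp_split_set,
    oversimulate_and_trim,
    parse_newick,
    random_jc_tree,
    random_topology,
    simulate_jc_alignment,
)
from dpvt.parsimony import CapabilityError
from dpvt.simulate import FilterError
from dpvt.dataset import load_dataset, save_dataset


def _tree_with_lengths(n, rng, length):
    t = random_topology(n, rng)
    for node in t.nodes:
        if node.parent is not None:
            node.length = length
    return t


class TestJCSimulation:
    def test_zero_lengths_give_identical_sequences(self, rng):
        t = _tree_with_lengths(6, rng, 0.0)
        aln = simulate_jc_alignment(t, 50, rng)
        assert len(set(aln.sequences.values())) == 1

    def test_negative_length_rejected(self, rng):
        t = _tree_with_lengths(4, rng, -0.1)
        with pytest.raises(ValueError):
            simulate_jc_alignment(t, 5, rng)

    def test_two_leaf_divergence_matches_closed_form(self, rng):
        """Choose t so P(differ) = 0.3 and check the empirical mismatch."""

        p = 0.3
        t_branch = -0.75 * np.log(1 - 4 * p / 3)
        tree = parse_newick("(B)A;")
        tree.node_by_label("B").length = t_branch
        n = 10_000
        aln = simulate_jc_alignment(tree, n, rng)
        a, b = aln.sequences["A"], aln.sequences["B"]
        mism = sum(x != y for x, y in zip(a, b)) / n
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(mism - p) < 3 * sigma

    def test_saturated_branch_approaches_uniform(self, rng):
        tree = parse_newick("(B)A;")
        tree.node_by_label("B").length = 50.0
        n = 10_000
        aln = simulate_jc_alignment(tree, n, rng)
        match = sum(
            x == y for x, y in zip(aln.sequences["A"], aln.sequences["B"])
        ) / n
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert abs(match - 0.25) < 3 * sigma

    def test_true_node_sequences_returned_on_request(self, rng):
        t = random_jc_tree(5, rng)
        aln, nodes = simulate_jc_alignment(t, 10, rng, return_node_sequences=True)
        assert set(nodes) == {n.index for n in t.nodes}
        assert nodes[0] == aln.sequences[t.root.label]


class TestFiltering:
    def test_constant_site_removed(self):
        aln = {"a": "AG", "b": "AC", "c": "AT", "d": "AA"}
        out = filter_alignment(aln)
        assert out.n_sites == 1

    def test_single_deviation_site_removed(self):
        # AAAC pattern: one sequence differs from all others
        aln = {"a": "AAG", "b": "AAC", "c": "ACT", "d": "CAA"}
        # site 0: A,A,A,C -> removed; site 1: A,A,C,A -> removed; site 2 kept
        out = filter_alignment(aln)
        assert out.n_sites == 1

    def test_two_two_sites_kept(self):
        # both sites split the sequences 2/2: parsimony-informative
        aln = {"a": "AG", "b": "AT", "c": "CG", "d": "CT"}
        out = filter_alignment(aln)
        assert out.n_sites == 2
        assert out.n_sequences == 4

    def test_gap_and_ambiguity_sites_removed(self):
        aln = {"a": "-AAG", "b": "ANAT", "c": "ACCG", "d": "ACCT"}
        out = filter_alignment(aln)
        assert out.n_sites == 2  # the '-' site and the 'N' site are dropped

    def test_duplicate_sequences_removed(self):
        aln = {"a": "AG", "b": "AT", "c": "CG", "d": "CT", "e": "AG"}
        out = filter_alignment(aln)
        assert out.n_sequences == 4
        assert out.n_sites == 2

    def test_everything_filtered_raises(self):
        with pytest.raises(FilterError):
            filter_alignment({"a": "AAAA", "b": "AAAA", "c": "AAAT"})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        chars = np.array(list("ACGT-N"))
        n, m = int(rng.integers(4, 9)), int(rng.integers(8, 30))
        aln = {f"s{i}": "".join(rng.choice(chars, size=m)) for i in range(n)}
        try:
            once = filter_alignment(aln)
        except FilterError:
            return
        twice = filter_alignment(once)
        assert twice.sequences == once.sequences


class TestOversimulateAndTrim:
    @pytest.mark.parametrize("n,sites", [(8, 40), (10, 25)])
    def test_exact_target_dimensions(self, n, sites, rng):
        aln = oversimulate_and_trim(SimulationSpec(n_sequences=n, n_sites=sites), rng)
        assert aln.n_sequences == n
        assert aln.n_sites == sites
        # the result is fully filtered
        assert filter_alignment(aln).sequences == aln.sequences

    def test_degenerate_rate_exhausts_retries(self, rng):
        spec = SimulationSpec(
            n_sequences=6, n_sites=10, branch_length_mean=1e-9, max_retries=3
        )
        with pytest.raises(FilterError):
            oversimulate_and_trim(spec, rng)


class TestDatasetGeneration:
    def test_exact_labels_match_independent_recomputation(self):
        spec = SimulationSpec(n_sequences=7, n_sites=20)
        rng = np.random.default_rng(77)
        examples = generate_labeled_dataset(
            spec, 2, PerturbationSpec(kind="spr"), rng, max_trees=4
        )
        assert examples
        by_alignment = {}
        for ex in examples:
            # re-derive the label vector from scratch: parse the tree,
            # rebuild the alignment from the leaf node sequences, enumerate
            tree = parse_newick(ex.newick, root_leaf=ex.meta["root_label"])
            aln = Alignment(
                {
                    leaf.label: ex.node_sequences[leaf.index]
                    for leaf in tree.leaves
                }
            )
            key = ex.meta["alignment_id"]
            if key not in by_alignment:
                by_alignment[key] = mp_split_set(enumerate_mp_trees(aln))
            fresh = label_edges(tree, by_alignment[key])
            assert (fresh.labels == ex.labels).all()

    def test_master_seed_reproducibility(self, tmp_path):
        spec = SimulationSpec(n_sequences=7, n_sites=15)
        pert = PerturbationSpec(kind="spr")
        a = generate_labeled_dataset(spec, 1, pert, np.random.default_rng(9), max_trees=3)
        b = generate_labeled_dataset(spec, 1, pert, np.random.default_rng(9), max_trees=3)
        save_dataset(a, tmp_path / "a")
        save_dataset(b, tmp_path / "b")
        for pa, pb in zip(sorted((tmp_path / "a").glob("example_*.json")),
                          sorted((tmp_path / "b").glob("example_*.json"))):
            assert pa.read_bytes() == pb.read_bytes()

    def test_exact_mode_capability_guard(self, rng):
        spec = SimulationSpec(n_sequences=30, n_sites=10)
        with pytest.raises(CapabilityError):
            generate_labeled_dataset(spec, 1, PerturbationSpec(), rng)

    def test_round_trip_serialization_lossless(self, tmp_path):
        spec = SimulationSpec(n_sequences=7, n_sites=15)
        examples = generate_labeled_dataset(
            spec, 1, PerturbationSpec(kind="union"), np.random.default_rng(4),
            max_trees=3,
        )
        save_dataset(examples, tmp_path / "ds", manifest={"seed": 4})
        loaded = load_dataset(tmp_path / "ds")
        assert len(loaded) == len(examples)
        for a, b in zip(examples, loaded):
            assert a.newick == b.newick
            assert (a.traversals.entries == b.traversals.entries).all()
            assert (a.mutations.entries == b.mutations.entries).all()
            assert (a.full_mutations == b.full_mutations).all()
            assert (a.labels == b.labels).all()
            assert a.node_sequences == b.node_sequences
        manifest = json.loads((tmp_path / "ds" / "manifest.json").read_text())
        assert manifest["count"] == len(examples)
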