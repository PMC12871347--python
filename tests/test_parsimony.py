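"""Fitch scoring/reconstruction against brute force; MP enumeration; labels."""

import numpy as np
import pytest

from dpvt import (
    Alignment,
    CapabilityError,
    enumerate_mp_trees,
    fitch_reconstruct,
    fitch_score,
    heuristic_mp_search,
    label_edges,
    mp_split_set,
    parse_newick,
    random_topology,
    root_at_leaf,
)
from dpvt.trees import Split

from conftest import brute_force_parsimony, enumerate_topologies, random_alignment


class TestFitchScore:
    def test_one_informative_site(self, quartet):
        aln = Alignment({"A": "A", "B": "A", "C": "C", "D": "C"})
        assert fitch_score(quartet, aln) == 1
        assert brute_force_parsimony(quartet, aln) == 1

    def test_constant_site_scores_zero(self, rng):
        t = random_topology(6, rng)
        aln = Alignment({l: "AAAA" for l in sorted(t.leaf_labels)})
        assert fitch_score(t, aln) == 0

    def test_all_different_states_on_every_quartet_topology(self):
        aln = Alignment({"A": "A", "B": "C", "C": "G", "D": "T"})
        for t in enumerate_topologies("ABCD"):
            assert fitch_score(t, aln) == 3
            assert brute_force_parsimony(t, aln) == 3

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 7))
            t = random_topology(n, rng)
            aln = random_alignment(t.leaf_labels, int(rng.integers(1, 8)), rng)
            assert fitch_score(t, aln) == brute_force_parsimony(t, aln)

    def test_invariant_to_root_choice(self, rng):
        t = random_topology(7, rng)
        aln = random_alignment(t.leaf_labels, 12, rng)
        ref = fitch_score(t, aln)
        for leaf in sorted(t.leaf_labels):
            assert fitch_score(root_at_leaf(t, leaf), aln) == ref

    def test_per_site_scores_sum_to_total(self, rng):
        t = random_topology(8, rng)
        aln = random_alignment(t.leaf_labels, 15, rng)
        per_site = fitch_score(t, aln, per_site=True)
        assert per_site.shape == (15,)
        assert per_site.sum() == fitch_score(t, aln)

    def test_label_mismatch_rejected(self, quartet):
        aln = Alignment({"A": "A", "B": "A", "X": "C", "D": "C"})
        with pytest.raises(ValueError):
            fitch_score(quartet, aln)


class TestFitchReconstruct:
    def test_unique_optimum_recovered(self, quartet):
        aln = Alignment({"A": "A", "B": "A", "C": "C", "D": "C"})
        hist = fitch_reconstruct(quartet, aln)
        assert hist.total_events == 1
        (edge,) = [i for i, ev in hist.events.items() if ev]
        assert hist.events[edge][0] == (0, "A", "C")

    def test_constant_site_has_no_events(self, rng):
        t = random_topology(5, rng)
        aln = Alignment({l: "GG" for l in sorted(t.leaf_labels)})
        assert fitch_reconstruct(t, aln).total_events == 0

    def test_event_count_equals_fitch_score(self, rng):
        """The tie-broken reconstruction achieves the optimal score exactly."""

        for _ in range(25):
            n = int(rng.integers(4, 7))
            t = random_topology(n, rng)
            aln = random_alignment(t.leaf_labels, int(rng.integers(1, 10)), rng)
            hist = fitch_reconstruct(t, aln)
            assert hist.total_events == fitch_score(t, aln)
            assert hist.total_events == brute_force_parsimony(t, aln)

    def test_root_keeps_own_sequence_and_events_match_diffs(self, rng):
        t = random_topology(6, rng)
        aln = random_alignment(t.leaf_labels, 8, rng)
        hist = fitch_reconstruct(t, aln)
        assert hist.node_sequences[0] == aln.sequences[t.root.label]
        for node in t.nodes:
            if node.parent is None:
                continue
            p, c = hist.node_sequences[node.parent.index], hist.node_sequences[node.index]
            diffs = [(k, p[k], c[k]) for k in range(len(c)) if p[k] != c[k]]
            assert diffs == hist.events[node.index]

    def test_deterministic(self, rng):
        t = random_topology(6, rng)
        aln = random_alignment(t.leaf_labels, 10, rng)
        a = fitch_reconstruct(t, aln)
        b = fitch_reconstruct(t, aln)
        assert a.node_sequences == b.node_sequences


class TestEnumerateMPTrees:
    def test_strong_signal_gives_unique_topology(self):
        aln = Alignment(
            {"A": "AACCG", "B": "AACCG", "C": "CCAAG", "D": "CCAAG"}
        )
        trees = enumerate_mp_trees(aln)
        assert len(trees) == 1
        assert mp_split_set(trees) == frozenset(
            [Split.of({"A", "B"}, {"A", "B", "C", "D"})]
        )

    def test_constant_alignment_makes_every_topology_optimal(self):
        aln = Alignment({l: "AAAA" for l in "ABCDE"})
        trees = enumerate_mp_trees(aln)
        assert len(trees) == 15  # (2n-5)!! for n=5
        assert len(mp_split_set(trees)) == 10  # all splits with both sides >= 2

    def test_equals_argmin_over_independent_enumeration(self, rng):
        labels = list("ABCDEF")
        aln = random_alignment(labels, 12, rng)
        expected = set()
        best = None
        for t in enumerate_topologies(labels):
            s = fitch_score(t, aln)
            if best is None or s < best:
                best, expected = s, {t.internal_splits()}
            elif s == best:
                expected.add(t.internal_splits())
        got = {t.internal_splits() for t in enumerate_mp_trees(aln)}
        assert got == expected

    def test_scores_partition_correctly(self, rng):
        """Every returned topology is optimal; every other is strictly worse."""

        labels = list("ABCDEF")
        aln = random_alignment(labels, 10, rng)
        mp = enumerate_mp_trees(aln)
        best = fitch_score(mp[0], aln)
        mp_keys = {t.internal_splits() for t in mp}
        for t in enumerate_topologies(labels):
            s = fitch_score(t, aln)
            if t.internal_splits() in mp_keys:
                assert s == best
            else:
                assert s > best

    def test_capability_error_beyond_max_n(self, rng):
        aln = random_alignment([f"s{i}" for i in range(12)], 4, rng)
        with pytest.raises(CapabilityError, match="heuristic"):
            enumerate_mp_trees(aln, max_n=10)


class TestHeuristicSearch:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_exact_mp_set_on_signal_bearing_alignments(self, seed):
        """On JC-simulated alignments (the pipeline's regime, where the
        parsimony landscape has real signal) the SPR hill-climb plateau
        matches exhaustive enumeration at n=7."""

        from dpvt import SimulationSpec, oversimulate_and_trim

        rng = np.random.default_rng(seed)
        aln = oversimulate_and_trim(SimulationSpec(n_sequences=7, n_sites=30), rng)
        exact = enumerate_mp_trees(aln)
        found = heuristic_mp_search(aln, np.random.default_rng(seed + 100), n_starts=2)
        assert min(fitch_score(t, aln) for t in found) == fitch_score(exact[0], aln)
        assert {t.internal_splits() for t in found} == {
            t.internal_splits() for t in exact
        }


class TestEdgeLabels:
    def test_mp_topology_labels_all_zero(self):
        aln = Alignment({"A": "AACC", "B": "AACC", "C": "CCAA", "D": "CCAA"})
        (tree,) = enumerate_mp_trees(aln)
        labels = label_edges(tree, mp_split_set([tree]))
        assert labels.labels.tolist() == [0]

    def test_split_set_union_algebra(self, rng):
        t1 = random_topology(6, rng)
        t2 = random_topology(6, rng)
        union = mp_split_set([t1, t2])
        s1, s2 = t1.internal_splits(), t2.internal_splits()
        assert len(union) == len(s1) + len(s2) - len(s1 & s2)

    def test_empty_split_set_rejected(self, quartet):
        with pytest.raises(ValueError):
            label_edges(quartet, frozenset())

    def test_leaf_set_mismatch_rejected(self, quartet, rng):
        other = random_topology(5, rng)
        with pytest.raises(ValueError):
            label_edges(quartet, other.internal_splits())
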