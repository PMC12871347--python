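"""Forward-pass semantics of the traversal network and pooling."""

import numpy as np
import pytest

from dpvt import DPVTNet, batch_examples, random_topology
from dpvt._autodiff import Tensor, bce_with_logits
from dpvt.model import pool_sites, _TransformerEncoderLayer

from conftest import random_alignment
from test_encoding import make_example


def _zeroed(net):
    for p in net.parameters():
        p.data = np.zeros_like(p.data)
    return net


class TestForwardSemantics:
    def test_zero_weights_give_half_probabilities(self, rng):
        _, _, ex = make_example(7, 10, rng)
        net = _zeroed(DPVTNet(feature_dim=8, hidden_dim=12, seed=0))
        assert np.allclose(net.predict_proba(ex), 0.5)

    def test_zero_mutations_and_biases_give_constant_logits(self, rng):
        """Pendant zero-initialisation: with no mutations anywhere the
        recurrent unit maps zero to zero (biases are zero at init), so all
        edges receive identical features and logits."""

        _, _, ex = make_example(9, 8, rng)
        net = DPVTNet(feature_dim=8, hidden_dim=12, seed=1)
        full = np.zeros_like(ex.full_mutations)
        logits = net.forward_example(ex.traversals.entries, full).data
        assert np.allclose(logits, logits[0])

    def test_quartet_matches_hand_unrolled_units(self, rng):
        """n=4: one internal edge; both passes are single unit applications
        reproducible directly from the weight matrices."""

        _, _, ex = make_example(4, 6, rng)
        net = DPVTNet(feature_dim=5, hidden_dim=7, seed=2)
        trav = ex.traversals.entries
        full = ex.full_mutations.astype(np.float64)
        (xu, yu, vu) = trav[0, 0]
        (xd, yd, vd) = trav[1, 0]

        def unit(u, inp):
            h = np.maximum(inp @ u.lin1.W.data + u.lin1.b.data, 0.0)
            return h @ u.lin2.W.data + u.lin2.b.data

        zero = np.zeros((6, 5))
        f_up = unit(net.up_unit, np.concatenate(
            [zero, -full[xu], zero, -full[yu]], axis=1))
        f_down = unit(net.down_unit, np.concatenate(
            [zero, full[vd], zero, -full[yd]], axis=1))
        feat = np.concatenate([f_up, f_down], axis=1).mean(axis=0)
        logit = feat @ net.classifier.W.data[:, 0] + net.classifier.b.data[0]
        got = net.forward_example(trav, ex.full_mutations).data
        assert np.allclose(got, [logit])

    def test_site_permutation_equivariance(self, rng):
        """Step 1 treats sites independently and no pooling mode uses site
        order, so permuting sites leaves pooled outputs unchanged."""

        _, _, ex = make_example(8, 9, rng)
        perm = np.random.default_rng(0).permutation(9)
        for mode in ("average", "max", "transformer"):
            net = DPVTNet(feature_dim=6, hidden_dim=8, pooling=mode,
                          transformer_heads=2, transformer_ff=16, seed=3)
            base = net.forward_example(ex.traversals.entries, ex.full_mutations).data
            permuted = net.forward_example(
                ex.traversals.entries, ex.full_mutations[:, perm, :]
            ).data
            assert np.allclose(base, permuted, atol=1e-10), mode

    def test_sensitive_to_mutation_magnitude(self, rng):
        _, _, ex = make_example(7, 8, rng)
        net = DPVTNet(feature_dim=6, hidden_dim=8, seed=4)
        a = net.forward_example(ex.traversals.entries, ex.full_mutations).data
        b = net.forward_example(
            ex.traversals.entries, 2 * ex.full_mutations.astype(np.int16)
        ).data
        assert not np.allclose(a, b)

    def test_leaf_state_perturbation_reaches_every_edge(self, rng):
        """The concatenated feature of each edge uses information from both
        sides of the tree: flipping one leaf's state changes all logits."""

        from dpvt import Alignment, fitch_reconstruct
        from dpvt.simulate import build_example

        t = random_topology(6, rng)
        aln = random_alignment(t.leaf_labels, 5, rng)
        ex = build_example(t, aln, t.internal_splits())
        label = sorted(t.leaf_labels)[-1]
        seq = aln.sequences[label]
        flipped = "T" + seq[1:] if seq[0] != "T" else "A" + seq[1:]
        aln2 = Alignment({**aln.sequences, label: flipped})
        ex2 = build_example(t, aln2, t.internal_splits())
        net = DPVTNet(feature_dim=8, hidden_dim=10, seed=5)
        a = net.forward_example(ex.traversals.entries, ex.full_mutations).data
        b = net.forward_example(ex2.traversals.entries, ex2.full_mutations).data
        assert (np.abs(a - b) > 1e-12).all()

    def test_output_count_and_range(self, rng):
        for n in (4, 6, 10):
            _, _, ex = make_example(n, 7, rng)
            net = DPVTNet(feature_dim=6, hidden_dim=8, seed=6)
            p = net.predict_proba(ex)
            assert p.shape == (n - 3,)
            assert ((p > 0) & (p < 1)).all()


class TestPooling:
    def test_single_site_reduces_to_that_feature_in_all_modes(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(3, 1, 8))
        layer = _TransformerEncoderLayer(8, 2, 16, rng)
        for mode, enc in (("average", None), ("max", None), ("transformer", [layer])):
            out = pool_sites(Tensor(feats), mode, None, enc)
            assert np.allclose(out.data, feats[:, 0, :]), mode

    def test_identical_site_features_are_idempotent(self):
        one = np.random.default_rng(1).normal(size=(2, 1, 6))
        feats = np.repeat(one, 5, axis=1)
        for mode in ("average", "max"):
            out = pool_sites(Tensor(feats), mode)
            assert np.allclose(out.data, one[:, 0, :])

    def test_all_sites_masked_rejected(self):
        feats = Tensor(np.zeros((2, 4, 6)))
        with pytest.raises(ValueError):
            pool_sites(feats, "average", np.zeros(4, dtype=bool))

    def test_transformer_block_is_identity_at_init(self):
        rng = np.random.default_rng(2)
        layer = _TransformerEncoderLayer(8, 2, 16, rng)
        x = np.random.default_rng(3).normal(size=(2, 5, 8))
        out = layer(Tensor(x), np.ones(5, dtype=bool))
        assert np.allclose(out.data, x)


class TestMaskingAndBatching:
    @pytest.mark.parametrize("mode", ["average", "max", "transformer"])
    def test_padded_forward_is_bit_identical(self, mode, rng):
        _, _, ex = make_example(7, 6, rng)
        net = DPVTNet(feature_dim=6, hidden_dim=8, pooling=mode,
                      transformer_heads=2, transformer_ff=16, seed=7)
        plain = net.forward_example(ex.traversals.entries, ex.full_mutations).data
        padded_full = np.zeros((ex.full_mutations.shape[0], 11, 4), dtype=np.int8)
        padded_full[:, :6] = ex.full_mutations
        mask = np.zeros(11, dtype=bool)
        mask[:6] = True
        padded = net.forward_example(ex.traversals.entries, padded_full, mask).data
        assert (plain == padded).all()

    def test_single_example_batch_equals_unbatched(self, rng):
        _, _, ex = make_example(6, 8, rng)
        net = DPVTNet(feature_dim=6, hidden_dim=8, seed=8)
        batch = batch_examples([ex])
        _, probs = net.batch_loss(batch)
        assert np.allclose(probs[0], net.predict_proba(ex))

    def test_padded_edges_do_not_change_loss(self, rng):
        _, _, small = make_example(5, 6, rng)
        _, _, big = make_example(9, 6, rng)
        net = DPVTNet(feature_dim=6, hidden_dim=8, seed=9)
        loss_pair, _ = net.batch_loss(batch_examples([small, big]))
        l_small = net.forward_example(small.traversals.entries, small.full_mutations)
        l_big = net.forward_example(big.traversals.entries, big.full_mutations)
        per_edge = np.concatenate([
            bce_per_edge(l_small.data, small.labels),
            bce_per_edge(l_big.data, big.labels),
        ])
        assert np.isclose(float(loss_pair.data), per_edge.mean())


def bce_per_edge(z, y):
    return np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))


class TestCheckpointing:
    def test_state_dict_round_trip(self, rng, tmp_path):
        from dpvt.dataset import load_checkpoint, save_checkpoint

        _, _, ex = make_example(6, 7, rng)
        net = DPVTNet(feature_dim=6, hidden_dim=8, pooling="max", seed=10)
        save_checkpoint(net, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        assert back.config == net.config
        assert np.allclose(back.predict_proba(ex), net.predict_proba(ex))
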