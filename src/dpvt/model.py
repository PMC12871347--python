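"""The DPVT network: two-pass tree-traversal RNN, site pooling, classifier.

Step 1 learns a feature per (edge, site) with a recurrent unit — a
two-layer feed-forward network with a ReLU between the layers — applied
along the tree in a bottom-up then a top-down traversal.  Pendant-edge
features are initialised to zero; mutation encodings of edges consumed
"against" their root-away direction are negated.  Features from the two
passes are concatenated to width ``2 * feature_dim``.

Step 2 pools the per-site features of each edge into one feature (masked
average, masked elementwise maximum, or a transformer encoder over the site
axis followed by a masked average) and classifies it with a linear layer
and a sigmoid: the output is the probability that the edge is a non-MP
edge.

The up and down passes use separate recurrent-unit weights by default
(their inputs are differently signed and sourced); sharing is available via
``share_units=True``.  The transformer encoder uses a pre-norm block with
zero-initialised residual projections, so at initialisation it is exactly
the identity and all three pooling modes agree.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._autodiff import Tensor, bce_with_logits, concat, softmax, stack
from .encoding import BatchedExample, EncodedExample

__all__ = ["DPVTNet", "pool_sites", "POOLING_MODES"]

POOLING_MODES = ("average", "max", "transformer")


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero: bool = False, gain: float = 2.0):
        if zero:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, math.sqrt(gain / n_in), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> List[Tensor]:
        return [self.W, self.b]


class _RecurrentUnit:
    """Two-layer feed-forward network with ReLU, input 2*(d+4) -> d."""

    def __init__(self, feature_dim: int, hidden_dim: int, rng):
        self.lin1 = _Linear(2 * (feature_dim + 4), hidden_dim, rng)
        self.lin2 = _Linear(hidden_dim, feature_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())

    def parameters(self) -> List[Tensor]:
        return self.lin1.parameters() + self.lin2.parameters()


class _LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b

    def parameters(self) -> List[Tensor]:
        return [self.g, self.b]


class _TransformerEncoderLayer:
    """Pre-norm transformer block with zero-initialised residual projections.

    No positional encoding is used: alignment sites are exchangeable under
    parsimony, and the block must stay permutation-equivariant over sites.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.h = n_heads
        self.dh = d_model // n_heads
        self.ln1 = _LayerNorm(d_model)
        self.ln2 = _LayerNorm(d_model)
        self.wq = _Linear(d_model, d_model, rng, gain=1.0)
        self.wk = _Linear(d_model, d_model, rng, gain=1.0)
        self.wv = _Linear(d_model, d_model, rng, gain=1.0)
        self.wo = _Linear(d_model, d_model, rng, zero=True)
        self.ff1 = _Linear(d_model, d_ff, rng)
        self.ff2 = _Linear(d_ff, d_model, rng, zero=True)

    def _attention(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        e, n, dm = x.shape

        def _heads(t: Tensor) -> Tensor:
            return t.reshape(e, n, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = _heads(self.wq(x)), _heads(self.wk(x)), _heads(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))
        neg = np.where(key_mask, 0.0, -1e9).reshape(1, 1, 1, n)
        attn = softmax(scores + Tensor(neg), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(e, n, dm)
        return self.wo(out)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = x + self._attention(self.ln1(x), key_mask)
        x = x + self.ff2(self.ff1(self.ln2(x)).relu())
        return x

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for part in (self.ln1, self.ln2, self.wq, self.wk, self.wv,
                     self.wo, self.ff1, self.ff2):
            out += part.parameters()
        return out


def pool_sites(features: Tensor, mode: str, site_mask: Optional[np.ndarray] = None,
               encoder_layers: Optional[Sequence[_TransformerEncoderLayer]] = None
               ) -> Tensor:
    """Aggregate per-site features (E, N, d) into per-edge features (E, d).

    Masked sites contribute nothing: the average divides by the number of
    real sites, the maximum ignores masked positions, and the transformer
    masks them out of every attention distribution before the final masked
    average.
    """

    if mode not in POOLING_MODES:
        raise ValueError(f"unknown pooling mode {mode!r}")
    n = features.shape[1]
    if site_mask is None:
        site_mask = np.ones(n, dtype=bool)
    site_mask = np.asarray(site_mask, dtype=bool)
    count = site_mask.sum()
    if count == 0:
        raise ValueError("all sites are masked")

    if mode == "transformer":
        if encoder_layers is None:
            raise ValueError("transformer pooling needs encoder layers")
        for layer in encoder_layers:
            features = layer(features, site_mask)
        mode = "average"

    if mode == "average":
        w = site_mask.astype(np.float64).reshape(1, n, 1)
        return (features * Tensor(w)).sum(axis=1) * (1.0 / count)
    # masked elementwise maximum
    neg = np.where(site_mask, 0.0, -1e30).reshape(1, n, 1)
    return (features + Tensor(neg)).max(axis=1)


class DPVTNet:
    """Trainable parameters and forward pass of the edge classifier."""

    def __init__(
        self,
        feature_dim: int = 64,
        hidden_dim: int = 256,
        pooling: str = "average",
        share_units: bool = False,
        transformer_layers: int = 1,
        transformer_heads: int = 4,
        transformer_ff: int = 512,
        seed: int = 0,
    ):
        if pooling not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {pooling!r}")
        self.config = dict(
            feature_dim=feature_dim,
            hidden_dim=hidden_dim,
            pooling=pooling,
            share_units=share_units,
            transformer_layers=transformer_layers,
            transformer_heads=transformer_heads,
            transformer_ff=transformer_ff,
            seed=seed,
        )
        self.feature_dim = feature_dim
        self.pooling = pooling
        rng = np.random.default_rng(seed)
        self.up_unit = _RecurrentUnit(feature_dim, hidden_dim, rng)
        self.down_unit = (
            self.up_unit if share_units
            else _RecurrentUnit(feature_dim, hidden_dim, rng)
        )
        self.encoder_layers: List[_TransformerEncoderLayer] = []
        if pooling == "transformer":
            for _ in range(transformer_layers):
                self.encoder_layers.append(
                    _TransformerEncoderLayer(
                        2 * feature_dim, transformer_heads, transformer_ff, rng
                    )
                )
        self.classifier = _Linear(2 * feature_dim, 1, rng, gain=1.0)

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> List[Tensor]:
        out = self.up_unit.parameters()
        if self.down_unit is not self.up_unit:
            out += self.down_unit.parameters()
        for layer in self.encoder_layers:
            out += layer.parameters()
        out += self.classifier.parameters()
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match model architecture")
            p.data = arr.copy()

    # -- forward -------------------------------------------------------------

    def upward_pass(self, traversals: np.ndarray, full_mutations: np.ndarray
                    ) -> Dict[int, Tensor]:
        """Bottom-up features f^u keyed by edge lower-node index."""

        n_sites = full_mutations.shape[1]
        zero = Tensor(np.zeros((n_sites, self.feature_dim)))
        mut = {i: Tensor(-full_mutations[i].astype(np.float64))
               for i in np.unique(traversals[0, :, :2])}
        f_up: Dict[int, Tensor] = {}
        for x, y, v in traversals[0]:
            inp = concat(
                [f_up.get(x, zero), mut[x], f_up.get(y, zero), mut[y]], axis=1
            )
            f_up[int(v)] = self.up_unit(inp)
        return f_up

    def downward_pass(self, traversals: np.ndarray, full_mutations: np.ndarray,
                      f_up: Dict[int, Tensor]) -> Dict[int, Tensor]:
        """Top-down features f^d keyed by edge lower-node index.

        For a visited edge with upper node v and sibling-edge child y, the
        inputs are the parent edge's downward feature and (un-negated)
        mutation encoding, addressed by v, and the sibling edge's upward
        feature and negated mutation encoding, addressed by y.  The visited
        edge's own lower node is the k-th smallest lower-node index of
        slice 0, since the top-down visit order is a preorder.
        """

        n_sites = full_mutations.shape[1]
        zero = Tensor(np.zeros((n_sites, self.feature_dim)))
        lower_nodes = np.sort(traversals[0, :, 2])
        f_down: Dict[int, Tensor] = {}
        for k, (x, y, v) in enumerate(traversals[1]):
            ma = Tensor(full_mutations[v].astype(np.float64))
            mb = Tensor(-full_mutations[y].astype(np.float64))
            inp = concat(
                [f_down.get(int(v), zero), ma, f_up.get(int(y), zero), mb], axis=1
            )
            f_down[int(lower_nodes[k])] = self.down_unit(inp)
        return f_down

    def classify_edges(self, pooled: Tensor) -> Tensor:
        """Per-edge logits from pooled features; sigmoid gives P(non-MP)."""

        e = pooled.shape[0]
        return self.classifier(pooled).reshape(e)

    def forward_example(
        self,
        traversals: np.ndarray,
        full_mutations: np.ndarray,
        site_mask: Optional[np.ndarray] = None,
    ) -> Tensor:
        """Logits for the internal edges of one tree (ascending child index)."""

        if traversals.shape[1] == 0:
            raise ValueError("tree has no internal edges (fewer than four leaves)")
        f_up = self.upward_pass(traversals, full_mutations)
        f_down = self.downward_pass(traversals, full_mutations, f_up)
        order = np.sort(traversals[0, :, 2])
        per_site = stack(
            [concat([f_up[int(w)], f_down[int(w)]], axis=1) for w in order], axis=0
        )
        pooled = pool_sites(per_site, self.pooling, site_mask, self.encoder_layers)
        return self.classify_edges(pooled)

    def predict_proba(self, example: EncodedExample) -> np.ndarray:
        """Per-internal-edge probability of being a non-MP edge."""

        logits = self.forward_example(
            example.traversals.entries, example.full_mutations
        )
        return 1.0 / (1.0 + np.exp(-logits.data))

    def batch_loss(self, batch: BatchedExample) -> Tuple[Tensor, np.ndarray]:
        """Masked BCE over all unmasked internal edges of a batch.

        Returns the scalar loss tensor and the per-edge probabilities
        (aligned with the batch's edge padding) for inspection.
        """

        logits_list = []
        for i in range(batch.n_examples):
            trav = batch.traversals[i]
            logits = self.forward_example(
                trav, batch.full_mutations[i], batch.site_mask[i]
            )
            ne = trav.shape[1]
            pad = batch.labels.shape[1] - ne
            if pad:
                logits = concat([logits, Tensor(np.zeros(pad))], axis=0)
            logits_list.append(logits)
        all_logits = stack(logits_list, axis=0)
        loss = bce_with_logits(all_logits, batch.labels, batch.edge_mask)
        probs = 1.0 / (1.0 + np.exp(-all_logits.data))
        return loss, probs
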