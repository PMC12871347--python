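"""Training loop, evaluation metrics, and the reversion baseline.

Training minimises masked binary cross-entropy with Adam (defaults:
learning rate 5e-5, batch size 4, up to 200 epochs) and early-stops when
the validation loss has not improved for five consecutive epochs, returning
the best-validation-loss checkpoint.  Pendant edges never enter the loss —
their splits are trivial and present in every tree — and padded edges or
sites are masked out.

Evaluation pools the predicted probabilities of all unmasked internal edges
across all test trees into a single ranking and reports the area under the
ROC curve: the probability that a random non-MP edge scores above a random
MP edge.

The untrained baseline flags an edge as non-MP when any site carries a
reversion: a mutation back to a state already present at that site in an
ancestral sequence on the path to the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from ._autodiff import Adam
from .encoding import EncodedExample, batch_examples
from .model import DPVTNet
from .parsimony import MutationHistory
from .trees import RootedTree, internal_edges, parse_newick

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "masked_bce_loss",
    "train",
    "auroc",
    "baseline_reversion",
    "baseline_predictions",
]


@dataclass
class TrainConfig:
    """Hyperparameters; the defaults are the model's standard settings."""

    learning_rate: float = 5e-5
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 5
    feature_dim: int = 64
    hidden_dim: int = 256
    pooling: str = "average"
    share_units: bool = False
    transformer_layers: int = 1
    transformer_heads: int = 4
    transformer_ff: int = 512
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs", "patience",
                     "feature_dim", "hidden_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch] if self.best_epoch >= 0 else float("nan")


def masked_bce_loss(probabilities, labels, mask=None) -> float:
    """Mean binary cross-entropy over unmasked entries (from probabilities)."""

    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    m = np.ones_like(y) if mask is None else np.asarray(mask, dtype=np.float64)
    if m.sum() == 0:
        raise ValueError("no unmasked entries in loss")
    eps = 1e-12
    per = -(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))
    return float((per * m).sum() / m.sum())


def _split_validation(
    examples: Sequence[EncodedExample], fraction: float, rng: np.random.Generator
) -> Tuple[List[EncodedExample], List[EncodedExample]]:
    """Hold out a validation set at the alignment level.

    Examples derived from one alignment share MP-tree collections, so they
    stay on one side of the split.  With a single alignment (or none
    recorded) the split falls back to the example level.
    """

    groups: Dict[object, List[EncodedExample]] = {}
    for i, ex in enumerate(examples):
        groups.setdefault(ex.meta.get("alignment_id", i), []).append(ex)
    keys = list(groups)
    if len(keys) < 2:
        items = list(examples)
        if len(items) < 2:
            raise ValueError("need at least two examples to split off validation")
        order = rng.permutation(len(items))
        n_val = max(1, int(round(fraction * len(items))))
        val_ids = set(order[:n_val].tolist())
        train = [items[i] for i in range(len(items)) if i not in val_ids]
        val = [items[i] for i in sorted(val_ids)]
        return train, val
    order = rng.permutation(len(keys))
    n_val = max(1, int(round(fraction * len(keys))))
    val_keys = {keys[i] for i in order[:n_val]}
    train = [ex for k in keys if k not in val_keys for ex in groups[k]]
    val = [ex for k in keys if k in val_keys for ex in groups[k]]
    return train, val


def _epoch_loss(net: DPVTNet, examples: Sequence[EncodedExample],
                batch_size: int) -> float:
    total, count = 0.0, 0
    for i in range(0, len(examples), batch_size):
        batch = batch_examples(examples[i : i + batch_size])
        loss, _ = net.batch_loss(batch)
        n = int(batch.edge_mask.sum())
        total += float(loss.data) * n
        count += n
    return total / count


def train(
    examples: Sequence[EncodedExample],
    config: Optional[TrainConfig] = None,
    validation: Optional[Sequence[EncodedExample]] = None,
) -> Tuple[DPVTNet, TrainingHistory]:
    """Train a DPVT network; returns the best-validation-loss checkpoint.

    If *validation* is not given, a ``validation_fraction`` share of the
    alignments is held out.  Fully reproducible under ``config.seed``.
    """

    config = config or TrainConfig()
    examples = list(examples)
    if not examples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if validation is None:
        train_set, val_set = _split_validation(
            examples, config.validation_fraction, rng
        )
    else:
        train_set, val_set = examples, list(validation)
    if not train_set or not val_set:
        raise ValueError("empty training or validation split")

    net = DPVTNet(
        feature_dim=config.feature_dim,
        hidden_dim=config.hidden_dim,
        pooling=config.pooling,
        share_units=config.share_units,
        transformer_layers=config.transformer_layers,
        transformer_heads=config.transformer_heads,
        transformer_ff=config.transformer_ff,
        seed=config.seed,
    )
    opt = Adam(net.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    best_state = net.state_dict()
    best_val = float("inf")
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        running, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = batch_examples([train_set[j] for j in order[i : i + config.batch_size]])
            loss, _ = net.batch_loss(batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            n = int(batch.edge_mask.sum())
            running += float(loss.data) * n
            seen += n
        history.train_loss.append(running / seen)
        val = _epoch_loss(net, val_set, config.batch_size)
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_state = net.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    history.stopped_epoch = len(history.val_loss) - 1
    net.load_state_dict(best_state)
    return net, history


def auroc(scores, labels, mask=None) -> float:
    """Pooled rank-based AUROC over unmasked entries.

    Raises if only one class is present (the curve is undefined).
    """

    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        s, y = s[m], y[m]
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(y, s))


# ---------------------------------------------------------------------------
# Reversion baseline
# ---------------------------------------------------------------------------


def baseline_reversion(
    tree: RootedTree, node_sequences: Dict[int, str]
) -> np.ndarray:
    """Untrained per-edge 0/1 predictions from reversion events.

    An internal edge is predicted non-MP (1) iff some site mutates on it to
    a state that already occurs at that site in a strict ancestor of the
    edge's upper endpoint.  Entries align with the preorder internal-edge
    order.
    """

    for node in tree.nodes:
        if node.index not in node_sequences:
            raise ValueError(f"missing sequence for node {node.index}")
    out = []
    for w in internal_edges(tree, "preorder"):
        u = w.parent
        child_seq = node_sequences[w.index]
        parent_seq = node_sequences[u.index]
        flagged = 0
        for site in range(len(child_seq)):
            to_state = child_seq[site]
            if parent_seq[site] == to_state:
                continue  # no mutation at this site
            anc = u.parent
            while anc is not None:
                if node_sequences[anc.index][site] == to_state:
                    flagged = 1
                    break
                anc = anc.parent
            if flagged:
                break
        out.append(flagged)
    return np.array(out, dtype=np.int8)


def baseline_predictions(example: EncodedExample) -> np.ndarray:
    """Reversion-baseline predictions for a serialized encoded example."""

    root_label = example.meta.get("root_label")
    tree = parse_newick(example.newick, root_leaf=root_label)
    seqs = {int(k): v for k, v in example.node_sequences.items()}
    return baseline_reversion(tree, seqs)
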