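"""High-level modelling interface: a Model built from data, a Results object.

`DPVTModel` wraps a labeled training set plus hyperparameters; `fit()`
trains the network and returns a :class:`DPVTResults` carrying the trained
parameters, training history, evaluation helpers, and a `summary()` table.

    >>> model = DPVTModel(train_examples, pooling="average")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.evaluate(test_examples)["auroc"]
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import EncodedExample
from .model import DPVTNet
from .parsimony import Alignment, fitch_reconstruct, label_edges, mp_split_set
from .simulate import build_example
from .train_eval import (
    TrainConfig,
    TrainingHistory,
    auroc,
    baseline_predictions,
    train,
)
from .trees import RootedTree, internal_edges, parse_newick, split_of_edge

__all__ = ["DPVTModel", "DPVTResults"]


class DPVTModel:
    """An edge-classification model specification bound to training data."""

    def __init__(
        self,
        examples: Sequence[EncodedExample],
        validation: Optional[Sequence[EncodedExample]] = None,
        config: Optional[TrainConfig] = None,
        **config_overrides,
    ):
        self.examples = list(examples)
        self.validation = list(validation) if validation is not None else None
        if config is None:
            config = TrainConfig(**config_overrides)
        elif config_overrides:
            raise ValueError("pass either a TrainConfig or keyword overrides, not both")
        self.config = config

    @classmethod
    def from_directory(cls, path, **kwargs) -> "DPVTModel":
        from .dataset import load_dataset

        return cls(load_dataset(path), **kwargs)

    def fit(self) -> "DPVTResults":
        net, history = train(self.examples, self.config, validation=self.validation)
        return DPVTResults(self, net, history)


class DPVTResults:
    """Fitted parameters, training history, and evaluation methods."""

    def __init__(self, model: DPVTModel, net: DPVTNet, history: TrainingHistory):
        self.model = model
        self.net = net
        self.history = history

    @property
    def params(self) -> Dict[str, np.ndarray]:
        return self.net.state_dict()

    # -- prediction ----------------------------------------------------------

    def predict_example(self, example: EncodedExample) -> np.ndarray:
        return self.net.predict_proba(example)

    def predict(self, tree: RootedTree, alignment: Alignment) -> pd.DataFrame:
        """Per-internal-edge non-MP probabilities for a candidate tree.

        Returns a table with the edge's child-node preorder index, its
        canonical split, the model probability, and the reversion-baseline
        flag.
        """

        history = fitch_reconstruct(tree, alignment)
        edges = internal_edges(tree, "preorder")
        dummy_labels = np.zeros(len(edges), dtype=np.int8)
        from .encoding import build_traversals, encode_all_edges, encode_mutations
        from .train_eval import baseline_reversion

        ex = EncodedExample(
            newick="",
            traversals=build_traversals(tree),
            mutations=encode_mutations(history, tree),
            full_mutations=encode_all_edges(history, tree),
            labels=dummy_labels,
            node_sequences=dict(history.node_sequences),
        )
        probs = self.net.predict_proba(ex)
        base = baseline_reversion(tree, history.node_sequences)
        return pd.DataFrame(
            {
                "child_index": [v.index for v in edges],
                "split": [str(split_of_edge(tree, v)) for v in edges],
                "probability": probs,
                "baseline": base,
            }
        )

    # -- evaluation ----------------------------------------------------------

    def evaluate(self, examples: Sequence[EncodedExample]) -> Dict[str, float]:
        """Pooled AUROC (model and baseline) and mean BCE on a test set."""

        from .train_eval import masked_bce_loss

        probs, base, labels = [], [], []
        for ex in examples:
            probs.append(self.predict_example(ex))
            base.append(baseline_predictions(ex))
            labels.append(ex.labels)
        p = np.concatenate(probs)
        b = np.concatenate(base)
        y = np.concatenate(labels)
        return {
            "auroc": auroc(p, y),
            "baseline_auroc": auroc(b, y),
            "bce": masked_bce_loss(p, y),
            "n_edges": int(len(y)),
            "n_trees": int(len(list(examples))),
        }

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        n_params = sum(p.size for p in self.params.values())
        lines = [
            "DPVT edge classifier — fit summary",
            "=" * 42,
            f"pooling:            {cfg.pooling}",
            f"feature dim:        {cfg.feature_dim} per direction",
            f"hidden dim:         {cfg.hidden_dim}",
            f"learning rate:      {cfg.learning_rate:g}",
            f"batch size:         {cfg.batch_size}",
            f"trainable params:   {n_params}",
            f"training examples:  {len(self.model.examples)}",
            f"epochs run:         {h.stopped_epoch + 1}",
            f"best epoch:         {h.best_epoch + 1}",
            f"best val loss:      {h.best_val_loss:.4f}",
            f"final train loss:   {h.train_loss[-1]:.4f}" if h.train_loss else "",
            "=" * 42,
        ]
        return "\n".join(l for l in lines if l)

    def save(self, path) -> None:
        from .dataset import save_checkpoint

        save_checkpoint(
            self.net,
            path,
            extra={
                "history": {
                    "train_loss": self.history.train_loss,
                    "val_loss": self.history.val_loss,
                    "best_epoch": self.history.best_epoch,
                }
            },
        )
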