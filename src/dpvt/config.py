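"""Configuration schema and the end-to-end pipeline runner.

Configurations are validated pydantic models (unknown keys rejected); the
defaults are the package's standard hyperparameters.  A single master seed
fans out to per-stage seeds through ``numpy.random.SeedSequence`` so every
stage is independently reproducible, and each pipeline run writes a
manifest (version, seeds, config snapshot, input hashes, stage timings)
from which its artifacts can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .perturb import PerturbationSpec
from .simulate import DEFAULT_BRANCH_LENGTH_MEAN, SimulationSpec
from .train_eval import TrainConfig

__all__ = [
    "PerturbationConfig",
    "DataConfig",
    "TrainingConfig",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "stage_seeds",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PerturbationConfig(_Strict):
    kind: Literal["spr", "bounded_subtree", "union"] = "spr"
    spr_count: Optional[int] = None
    depth: Optional[int] = None
    depth_fraction: float = 0.5
    target_fraction: float = 1.0 / 3.0
    max_attempts: int = 100

    def to_spec(self) -> PerturbationSpec:
        return PerturbationSpec(**self.model_dump())


class DataConfig(_Strict):
    n_sequences: int = 8
    n_sites: int = 30
    count: int = 20
    test_count: int = 5
    branch_length_mean: float = DEFAULT_BRANCH_LENGTH_MEAN
    labeling: Literal["exact", "heuristic"] = "exact"
    max_trees: int = 200
    max_exact_n: int = 10

    @model_validator(mode="after")
    def _capability(self):
        if self.labeling == "exact" and self.n_sequences > self.max_exact_n:
            raise ValueError(
                f"exact labeling is limited to n <= {self.max_exact_n} "
                f"sequences (got {self.n_sequences}); set labeling: heuristic"
            )
        return self

    def to_spec(self) -> SimulationSpec:
        return SimulationSpec(
            n_sequences=self.n_sequences,
            n_sites=self.n_sites,
            branch_length_mean=self.branch_length_mean,
        )


class TrainingConfig(_Strict):
    learning_rate: float = 5e-5
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 5
    feature_dim: int = 64
    hidden_dim: int = 256
    pooling: Literal["average", "max", "transformer"] = "average"
    share_units: bool = False
    transformer_layers: int = 1
    transformer_heads: int = 4
    transformer_ff: int = 512
    validation_fraction: float = 0.1

    def to_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class PipelineConfig(_Strict):
    seed: int = 0
    data: DataConfig = DataConfig()
    perturbation: PerturbationConfig = PerturbationConfig()
    training: TrainingConfig = TrainingConfig()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def stage_seeds(master_seed: int, n: int = 3):
    """Fan a master seed out to independent per-stage integer seeds (< 2^31)."""

    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _hash_directory(directory: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(directory.glob("*.json")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Dict:
    """simulate -> generate -> train -> evaluate, with a run manifest.

    Writes ``train_data/``, ``test_data/``, ``model.npz``, ``metrics.json``
    and ``manifest.json`` under *out_dir* and returns the metrics.
    """

    from . import __version__
    from .api import DPVTModel
    from .dataset import load_dataset, save_dataset
    from .simulate import generate_labeled_dataset

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_seed, test_seed, train_seed = stage_seeds(config.seed, 3)
    timings: Dict[str, float] = {}

    def _generate(seed: int, count: int, directory: Path):
        rng = np.random.default_rng(seed)
        examples = generate_labeled_dataset(
            config.data.to_spec(),
            count,
            config.perturbation.to_spec(),
            rng,
            max_trees=config.data.max_trees,
            labeling=config.data.labeling,
            max_exact_n=config.data.max_exact_n,
        )
        save_dataset(examples, directory, manifest={"seed": seed})
        return examples

    t0 = time.perf_counter()
    train_examples = _generate(gen_seed, config.data.count, out_dir / "train_data")
    timings["generate_train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    test_examples = _generate(test_seed, config.data.test_count, out_dir / "test_data")
    timings["generate_test"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = DPVTModel(train_examples, config=config.training.to_config(train_seed))
    results = model.fit()
    timings["train"] = time.perf_counter() - t0
    results.save(out_dir / "model.npz")

    t0 = time.perf_counter()
    metrics = results.evaluate(test_examples)
    metrics["best_epoch"] = results.history.best_epoch
    metrics["best_val_loss"] = results.history.best_val_loss
    timings["evaluate"] = time.perf_counter() - t0

    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    manifest = {
        "tool_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {
            "generate_train": gen_seed,
            "generate_test": test_seed,
            "train": train_seed,
        },
        "config": config.model_dump(),
        "input_hashes": {
            "train_data": _hash_directory(out_dir / "train_data"),
            "test_data": _hash_directory(out_dir / "test_data"),
        },
        "timings_seconds": timings,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return metrics
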