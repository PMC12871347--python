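"""On-disk formats: labeled example datasets and model checkpoints.

Each encoded example is one JSON file (Newick topology, traversal tensor,
mutation tensor, per-node mutation encodings, label vector, node sequences,
manifest) so a dataset directory is plain text and diffable; a
``manifest.json`` records dataset-level metadata.  Checkpoints are NumPy
``.npz`` archives holding the weight arrays plus a JSON-encoded model
configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np

from .encoding import EncodedExample, MutationTensor, TraversalTensor
from .model import DPVTNet

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1


def _example_to_dict(ex: EncodedExample) -> Dict:
    return {
        "newick": ex.newick,
        "traversals": ex.traversals.entries.tolist(),
        "mutation_entries": ex.mutations.entries.tolist(),
        "mutation_child_indices": ex.mutations.child_indices.tolist(),
        "full_mutations": ex.full_mutations.tolist(),
        "labels": ex.labels.tolist(),
        "node_sequences": {str(k): v for k, v in ex.node_sequences.items()},
        "meta": ex.meta,
    }


def _example_from_dict(d: Dict) -> EncodedExample:
    return EncodedExample(
        newick=d["newick"],
        traversals=TraversalTensor(np.array(d["traversals"], dtype=np.int64)),
        mutations=MutationTensor(
            np.array(d["mutation_entries"], dtype=np.int8),
            np.array(d["mutation_child_indices"], dtype=np.int64),
        ),
        full_mutations=np.array(d["full_mutations"], dtype=np.int8),
        labels=np.array(d["labels"], dtype=np.int8),
        node_sequences={int(k): v for k, v in d["node_sequences"].items()},
        meta=dict(d.get("meta", {})),
    )


def save_dataset(
    examples: Iterable[EncodedExample], directory, manifest: Optional[Dict] = None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    examples = list(examples)
    for i, ex in enumerate(examples):
        with open(directory / f"example_{i:05d}.json", "w") as fh:
            json.dump(_example_to_dict(ex), fh)
    info = {"format_version": FORMAT_VERSION, "count": len(examples)}
    info.update(manifest or {})
    with open(directory / "manifest.json", "w") as fh:
        json.dump(info, fh, indent=2)
    return directory


def load_dataset(directory) -> List[EncodedExample]:
    directory = Path(directory)
    paths = sorted(directory.glob("example_*.json"))
    if not paths:
        raise FileNotFoundError(f"no examples found in {directory}")
    out = []
    for p in paths:
        with open(p) as fh:
            out.append(_example_from_dict(json.load(fh)))
    return out


def save_checkpoint(net: DPVTNet, path, extra: Optional[Dict] = None) -> None:
    meta = {"format_version": FORMAT_VERSION, "config": net.config}
    meta.update(extra or {})
    np.savez(path, __meta__=np.array(json.dumps(meta)), **net.state_dict())


def load_checkpoint(path) -> DPVTNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net = DPVTNet(**meta["config"])
    net.load_state_dict(state)
    return net
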