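"""Single-file model checkpoints with the architecture config embedded."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from autograd.misc import flatten

from .cnn import CNNConfig, ResidualCNN
from .stgcn import STGCN, STGCNConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(model, path: str | Path) -> None:
    flat, _ = flatten(model.params)
    kind = "stgcn" if isinstance(model, STGCN) else "cnn"
    meta = {"kind": kind, "config": dataclasses.asdict(model.config)}
    payload = {"flat_params": flat, "meta": json.dumps(meta)}
    if kind == "stgcn":
        payload["adjacency"] = model.adjacency
    np.savez_compressed(path, **payload)


def load_checkpoint(path: str | Path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg = meta["config"]
        for key in ("input_branches", "block_channels", "stage_channels"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        if meta["kind"] == "stgcn":
            model = STGCN(STGCNConfig(**cfg), np.asarray(z["adjacency"]), seed=0)
        else:
            model = ResidualCNN(CNNConfig(**cfg), seed=0)
        _, unflatten = flatten(model.params)
        model.params = unflatten(np.asarray(z["flat_params"]))
    return model
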