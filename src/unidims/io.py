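"""HDF5 and YAML/JSON persistence for activations, brain matrices, and bases.

Layout of an activation container:

* one group per network, one dataset per layer, rows in stimulus order;
* a ``brain`` group with one dataset per subject;
* root attributes: ``seed``, ``config`` (JSON), and per-group ``split`` labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import yaml

from .activations import ActivationSet, PCBasis, PCScores

__all__ = [
    "write_world_h5",
    "read_activations_h5",
    "read_brain_h5",
    "write_pc_h5",
    "read_pc_h5",
    "load_config_file",
]


def write_world_h5(
    path: str | Path,
    networks: Mapping[str, ActivationSet],
    subjects: Sequence[np.ndarray] = (),
    config_json: str = "",
    seed: int | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        if config_json:
            f.attrs["config"] = config_json
        if seed is not None:
            f.attrs["seed"] = int(seed)
        for nid, actset in networks.items():
            g = f.create_group(f"networks/{nid}")
            g.attrs["split"] = actset.split
            g.attrs["layer_order"] = json.dumps(list(actset.layers))
            for lid, arr in actset.layers.items():
                g.create_dataset(lid, data=np.asarray(arr, dtype=np.float64))
        for s, V in enumerate(subjects):
            f.create_dataset(
                f"brain/subj{s}", data=np.asarray(V, dtype=np.float64)
            )


def read_activations_h5(path: str | Path) -> dict[str, ActivationSet]:
    out: dict[str, ActivationSet] = {}
    with h5py.File(path, "r") as f:
        for nid, g in f["networks"].items():
            order = json.loads(g.attrs.get("layer_order", json.dumps(list(g))))
            layers = {lid: g[lid][...] for lid in order}
            out[nid] = ActivationSet(
                network_id=nid, layers=layers, split=str(g.attrs.get("split", "all"))
            )
    return out


def read_brain_h5(path: str | Path) -> list[np.ndarray]:
    with h5py.File(path, "r") as f:
        if "brain" not in f:
            return []
        keys = sorted(f["brain"], key=lambda k: int(k.removeprefix("subj")))
        return [f[f"brain/{k}"][...] for k in keys]


def write_pc_h5(
    path: str | Path,
    bases: Mapping[str, Mapping[str, PCBasis]],
    scores: Mapping[str, Mapping[str, PCScores]],
) -> None:
    """Persist per-network, per-layer PC bases and evaluation-set scores."""
    with h5py.File(path, "w") as f:
        for nid, layers in bases.items():
            for lid, basis in layers.items():
                g = f.create_group(f"{nid}/{lid}")
                g.create_dataset("channel_means", data=basis.channel_means)
                g.create_dataset("loadings", data=basis.loadings)
                g.create_dataset("variances", data=basis.variances)
                g.attrs["rank"] = basis.rank
                ps = scores[nid][lid]
                g.create_dataset("scores", data=ps.scores)
                g.create_dataset("pc_rank", data=ps.pc_rank)


def read_pc_h5(
    path: str | Path,
) -> tuple[dict[str, dict[str, PCBasis]], dict[str, dict[str, PCScores]]]:
    bases: dict[str, dict[str, PCBasis]] = {}
    scores: dict[str, dict[str, PCScores]] = {}
    with h5py.File(path, "r") as f:
        for nid, netg in f.items():
            bases[nid], scores[nid] = {}, {}
            for lid, g in netg.items():
                bases[nid][lid] = PCBasis(
                    layer_id=lid,
                    channel_means=g["channel_means"][...],
                    loadings=g["loadings"][...],
                    variances=g["variances"][...],
                    rank=int(g.attrs["rank"]),
                )
                scores[nid][lid] = PCScores(
                    layer_id=lid,
                    scores=g["scores"][...],
                    pc_rank=g["pc_rank"][...],
                )
    return bases, scores


def load_config_file(path: str | Path) -> dict:
    """Load a configuration mapping from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
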