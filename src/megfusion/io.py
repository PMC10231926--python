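"""Serialization: HDF5 containers for arrays, TSV tables, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .conditions import condition_index
from .synthgen import (
    EffectWindow,
    EpochedDataset,
    RoiProfile,
    SimulationConfig,
)

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_rdms",
    "load_rdms",
    "save_betas",
    "load_betas",
    "config_to_yaml",
    "config_from_yaml",
    "condition_index_json",
]

_LABEL_COLS = ("exemplar", "category", "outcome")


def save_epochs(path, dataset: EpochedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.data, compression="gzip")
        f.create_dataset("time_ms", data=dataset.time_ms)
        f.attrs["sfreq_hz"] = dataset.sfreq_hz
        grp = f.create_group("labels")
        grp.create_dataset("exemplar", data=dataset.labels["exemplar"].to_numpy())
        for col in ("category", "outcome"):
            grp.create_dataset(
                col, data=np.array(dataset.labels[col], dtype=h5py.string_dtype())
            )


def load_epochs(path) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        labels = pd.DataFrame(
            {
                "exemplar": f["labels/exemplar"][()],
                "category": [s.decode() for s in f["labels/category"][()]],
                "outcome": [s.decode() for s in f["labels/outcome"][()]],
            }
        )
        return EpochedDataset(
            data=f["data"][()],
            time_ms=f["time_ms"][()],
            labels=labels,
            sfreq_hz=float(f.attrs["sfreq_hz"]),
        )


def condition_index_json() -> str:
    """The canonical 40-condition ordering as a JSON string."""
    return json.dumps(
        [dataclasses.asdict(c) for c in condition_index()], indent=1
    )


def save_rdms(path, rdms: np.ndarray, time_ms: np.ndarray | None = None) -> None:
    """RDM stack to HDF5, with the condition ordering as a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("rdms", data=np.asarray(rdms), compression="gzip")
        if time_ms is not None:
            f.create_dataset("time_ms", data=np.asarray(time_ms))
    path.with_suffix(path.suffix + ".conditions.json").write_text(
        condition_index_json()
    )


def load_rdms(path) -> tuple[np.ndarray, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        rdms = f["rdms"][()]
        time_ms = f["time_ms"][()] if "time_ms" in f else None
    return rdms, time_ms


def save_betas(path, betas: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for roi, arr in betas.items():
            f.create_dataset(roi, data=np.asarray(arr), compression="gzip")


def load_betas(path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {roi: f[roi][()] for roi in f}


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["roi_profiles"] = {
        roi: dataclasses.asdict(prof) for roi, prof in config.roi_profiles.items()
    }
    d["epoch_window_ms"] = list(config.epoch_window_ms)
    d["shrink_window_ms"] = list(config.shrink_window_ms)
    return d


def config_to_yaml(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def config_from_yaml(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("category_effect", "exemplar_effect", "two_state_offset"):
        if key in d and isinstance(d[key], dict):
            d[key] = EffectWindow(**d[key])
    if "roi_profiles" in d:
        d["roi_profiles"] = {
            roi: RoiProfile(**prof) if isinstance(prof, dict) else prof
            for roi, prof in d["roi_profiles"].items()
        }
    for key in ("epoch_window_ms", "shrink_window_ms"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
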