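"""File formats: HDF5 trace/patch records, CSV event tables, JSON ground
truth, YAML generator configs.

Layout of the HDF5 files mirrors common calcium/ephys conventions:
``/traces`` (neuron x time) or ``/voltage`` + ``/current``, a ``/time``
axis, and attributes ``sampling_rate``, ``state_label`` / ``group_label``.
Event tables are plain CSV with columns onset_s, offset_s, label, actor
(BORIS-style exports with those columns load directly).  Ground truth
travels as a JSON sidecar next to the data file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import EventTable, PatchRecord, TraceMatrix
from .synthgen import EthogramConfig, PatchConfig, PopulationConfig

__all__ = [
    "save_traces", "load_traces",
    "save_patch_record", "load_patch_record",
    "save_events", "load_events",
    "save_ground_truth",
    "load_population_config", "load_ethogram_config", "load_patch_config",
]


def save_traces(path: str | Path, tm: TraceMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=tm.traces)
        f.create_dataset("time", data=tm.time())
        f.create_dataset("neuron_ids", data=np.asarray(tm.neuron_ids))
        f.attrs["sampling_rate"] = tm.sampling_rate
        f.attrs["state_label"] = tm.state_label
        f.attrs["animal_id"] = tm.animal_id
        f.attrs["zscored"] = tm.zscored


def load_traces(path: str | Path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        return TraceMatrix(
            traces=f["traces"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            neuron_ids=f["neuron_ids"][()] if "neuron_ids" in f else None,
            state_label=str(f.attrs.get("state_label", "")),
            animal_id=str(f.attrs.get("animal_id", "")),
            zscored=bool(f.attrs.get("zscored", False)),
        )


def save_patch_record(path: str | Path, rec: PatchRecord) -> None:
    with h5py.File(path, "w") as f:
        if rec.voltage is not None:
            f.create_dataset("voltage", data=rec.voltage)
        if rec.current is not None:
            f.create_dataset("current", data=rec.current)
        f.create_dataset("time", data=rec.time())
        if rec.step_protocol:
            f.create_dataset("step_protocol", data=np.asarray(rec.step_protocol))
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["cell_id"] = rec.cell_id
        f.attrs["group_label"] = rec.group_label


def load_patch_record(path: str | Path) -> PatchRecord:
    with h5py.File(path, "r") as f:
        steps = [tuple(map(float, row)) for row in f["step_protocol"][()]] \
            if "step_protocol" in f else []
        return PatchRecord(
            voltage=f["voltage"][()] if "voltage" in f else None,
            current=f["current"][()] if "current" in f else None,
            sampling_rate=float(f.attrs["sampling_rate"]),
            step_protocol=steps,
            cell_id=str(f.attrs.get("cell_id", "")),
            group_label=str(f.attrs.get("group_label", "")),
        )


def save_events(path: str | Path, events: EventTable) -> None:
    events.df.to_csv(path, index=False)


def load_events(path: str | Path, **meta: Any) -> EventTable:
    df = pd.read_csv(path)
    return EventTable(df=df, meta=meta)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_ground_truth(path: str | Path, gt: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(_jsonable(gt), indent=1))


def _load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def load_population_config(path: str | Path) -> PopulationConfig:
    d = _load_yaml(path)
    if "tuning_matrix" in d and d["tuning_matrix"] is not None:
        d["tuning_matrix"] = np.asarray(d["tuning_matrix"], dtype=float)
    if "inter_bout_gap" in d:
        d["inter_bout_gap"] = tuple(d["inter_bout_gap"])
    return PopulationConfig(**d)


def load_ethogram_config(path: str | Path) -> EthogramConfig:
    d = _load_yaml(path)
    if "transition_matrix_true" in d and d["transition_matrix_true"] is not None:
        d["transition_matrix_true"] = np.asarray(d["transition_matrix_true"], dtype=float)
    return EthogramConfig(**d)


def load_patch_config(path: str | Path) -> PatchConfig:
    return PatchConfig(**_load_yaml(path))
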