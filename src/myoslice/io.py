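"""File formats: TIFF stacks with JSON sidecars, CSV traces and tables.

A stack is a multi-page TIFF (one page per z-plane) accompanied by
``<name>.json`` holding the voxel size (required -- distances are
meaningless without it), channel label and free metadata. A force trace is a
two-column CSV (time_s, force_mN) with a JSON sidecar carrying sampling
rate, protocol and stimulus times. Tables are plain CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import InvalidSpecError, VoxelStack
from .kinetics import ForceTrace

__all__ = [
    "write_stack",
    "read_stack",
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: VoxelStack) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    meta = {
        "voxel_size_um": list(stack.voxel_size_um),
        "channel_label": stack.channel_label,
        "metadata": {k: v for k, v in stack.metadata.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> VoxelStack:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidSpecError(f"missing sidecar {side.name}: voxel_size_um is required")
    meta = json.loads(side.read_text())
    if "voxel_size_um" not in meta:
        raise InvalidSpecError("sidecar lacks required field 'voxel_size_um'")
    return VoxelStack(
        intensities=tifffile.imread(path),
        voxel_size_um=tuple(meta["voxel_size_um"]),
        channel_label=meta.get("channel_label", ""),
        metadata=meta.get("metadata", {}),
    )


def write_distance_map(path: str | Path, distance_map: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(distance_map, dtype=np.float32))
    return path


def write_trace(path: str | Path, trace: ForceTrace) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "force_mN": trace.force_mN}).to_csv(path, index=False)
    meta = {
        "sampling_hz": trace.sampling_hz,
        "protocol": [list(iv) for iv in trace.protocol],
        "stimulus_times_s": None
        if trace.stimulus_times_s is None
        else list(map(float, trace.stimulus_times_s)),
        "metadata": {k: v for k, v in trace.metadata.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> ForceTrace:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidSpecError(f"missing sidecar {side.name}: sampling_hz/protocol required")
    meta = json.loads(side.read_text())
    df = pd.read_csv(path)
    for col in ("time_s", "force_mN"):
        if col not in df.columns:
            raise InvalidSpecError(f"trace CSV lacks required column {col!r}")
    stim = meta.get("stimulus_times_s")
    return ForceTrace(
        time_s=df["time_s"].to_numpy(),
        force_mN=df["force_mN"].to_numpy(),
        sampling_hz=float(meta["sampling_hz"]),
        protocol=tuple(tuple(iv) for iv in meta["protocol"]),
        stimulus_times_s=None if stim is None else np.asarray(stim, dtype=float),
        metadata=meta.get("metadata", {}),
    )


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
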