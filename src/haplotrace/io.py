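"""File-format helpers: TIFF stacks, trace tables, matrices with sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import VoxelVolume
from .polymer_sim import frame_to_traces, traces_to_frame

__all__ = [
    "save_volume",
    "load_volume",
    "save_traces",
    "load_traces",
    "save_matrix",
    "load_matrix",
]


def save_volume(path, volume: VoxelVolume) -> None:
    """Write a volume as a multi-page TIFF with voxel size metadata."""
    dx, dy, dz = volume.voxel_size
    tifffile.imwrite(
        str(path),
        np.asarray(volume.data),
        metadata={"spacing_um": [dx, dy, dz], "axes": "ZYX"},
    )


def load_volume(path, voxel_size=(0.1, 0.1, 0.2)) -> VoxelVolume:
    data = tifffile.imread(str(path))
    try:
        with tifffile.TiffFile(str(path)) as tf:
            meta = tf.shaped_metadata
            if meta and "spacing_um" in meta[0]:
                voxel_size = tuple(meta[0]["spacing_um"])
    except Exception:
        pass
    return VoxelVolume(data, voxel_size)


def save_traces(path, traces) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def load_traces(path, region_ids=None):
    return frame_to_traces(pd.read_csv(path), region_ids=region_ids)


def save_matrix(path, matrix: np.ndarray, region_coords=None) -> None:
    """Matrix as CSV with a JSON sidecar of region coordinates (Mb)."""
    path = Path(path)
    np.savetxt(path, matrix, delimiter=",")
    if region_coords is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"region_coords_mb": list(map(float, region_coords))})
        )


def load_matrix(path):
    path = Path(path)
    matrix = np.loadtxt(path, delimiter=",")
    coords = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        coords = np.asarray(json.loads(sidecar.read_text())["region_coords_mb"])
    return matrix, coords
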