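"""File I/O: TIFF volumes, centerline CSVs, config and summary JSON/YAML.

4D volumes are stored as multi-page TIFF in frame-major page order (page
index = t * nz + z); 3D volumes use one page per z-slice. Physical voxel
spacing is not carried by the TIFFs and travels in the sidecar JSON or
the pipeline config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import CenterlineGraph

__all__ = [
    "write_volume",
    "read_volume",
    "write_volume4d",
    "read_volume4d",
    "write_centerlines_csv",
    "write_truth_centerlines_csv",
    "load_config_file",
    "write_json",
]


def write_volume(path, volume: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(volume))


def read_volume(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_volume4d(path, frames: np.ndarray) -> None:
    """Write (t, z, y, x) data as a multi-page TIFF, frame-major page order."""
    frames = np.asarray(frames)
    if frames.ndim != 4:
        raise ValueError("expected 4D (t, z, y, x) data")
    t, z, y, x = frames.shape
    tifffile.imwrite(str(path), frames.reshape(t * z, y, x), metadata={"n_frames": t, "nz": z})


def read_volume4d(path, n_frames: int) -> np.ndarray:
    """Read a frame-major multi-page TIFF back into (t, z, y, x)."""
    pages = tifffile.imread(str(path))
    if pages.ndim != 3 or pages.shape[0] % n_frames:
        raise ValueError("page count is not a multiple of n_frames")
    nz = pages.shape[0] // n_frames
    return pages.reshape(n_frames, nz, *pages.shape[1:])


def write_centerlines_csv(path, graph: CenterlineGraph) -> None:
    rows = []
    for edge_id, pts in enumerate(graph.edge_polylines()):
        for i, (z, y, x) in enumerate(pts):
            rows.append((edge_id, i, z, y, x))
    pd.DataFrame(
        rows, columns=["edge_id", "point_index", "z_um", "y_um", "x_um"]
    ).to_csv(path, index=False)


def write_truth_centerlines_csv(path, centerlines_um: list[np.ndarray]) -> None:
    rows = []
    for tube_id, pts in enumerate(centerlines_um):
        for i, (z, y, x) in enumerate(pts):
            rows.append((tube_id, i, z, y, x))
    pd.DataFrame(
        rows, columns=["tube_id", "point_index", "z_um", "y_um", "x_um"]
    ).to_csv(path, index=False)


def load_config_file(path) -> dict:
    """Read a JSON or YAML mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
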