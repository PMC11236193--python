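"""Reading and writing stacks, label maps and result tables.

Stacks are written as one 16-bit multi-page TIFF per channel plus a JSON
sidecar (``stack.json``) holding voxel size and channel roles; ground
truth goes to a per-cell CSV plus a JSON sidecar for scene-level truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .segmentation import LabelMap
from .synthetic_data import GroundTruth, ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "write_labelmap",
    "read_labelmap",
]

STACK_META = "stack.json"


def write_stack(stack: ImageStack, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.channels.items():
        tifffile.imwrite(
            out / f"{name}.tif",
            np.clip(np.round(arr), 0, 65535).astype(np.uint16),
        )
    meta = {
        "voxel_size_um": list(stack.voxel_size_um),
        "channel_roles": dict(stack.channel_roles),
    }
    (out / STACK_META).write_text(json.dumps(meta, indent=2))
    return out


def read_stack(in_dir: str | Path) -> ImageStack:
    src = Path(in_dir)
    meta = json.loads((src / STACK_META).read_text())
    channels = {
        name: tifffile.imread(src / f"{name}.tif").astype(np.float64)
        for name in meta["channel_roles"]
    }
    return ImageStack(
        channels=channels,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        channel_roles=dict(meta["channel_roles"]),
    )


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.to_dataframe().to_csv(out / "ground_truth_cells.csv", index=False)
    scene = {
        "extent_um": list(truth.extent_um),
        "n_cells": len(truth),
        "band_thickness_um": truth.band_thickness_um,
    }
    (out / "ground_truth_scene.json").write_text(json.dumps(scene, indent=2))
    return out


def write_labelmap(labelmap: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labelmap.labels.astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"pixel_size_um": list(labelmap.pixel_size_um)}))
    return path


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    meta = json.loads(path.with_suffix(".json").read_text())
    return LabelMap(labels=labels, pixel_size_um=tuple(meta["pixel_size_um"]))
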