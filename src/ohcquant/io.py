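"""Readers and writers for image stacks and tabular inputs.

Images travel as multi-page TIFF with axes (C, Z, Y, X) — or (C, Y, X) for
single planes — accompanied by a JSON sidecar (``<stem>.json``) recording
channel names and the physical voxel size in μm, since plain TIFF has no
reliable slot for anisotropic 3D spacing.  Tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .recruitment import ImageStack

__all__ = ["write_stack", "read_stack", "sidecar_path"]


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_stack(stack: ImageStack, tiff_path) -> Path:
    """Write an ImageStack as channel-stacked TIFF plus JSON sidecar."""
    tiff_path = Path(tiff_path)
    names = sorted(stack.channels)
    data = np.stack([np.asarray(stack.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(tiff_path, data)
    meta = {
        "channels": names,
        "voxel_size_um": list(stack.voxel_size),
        "shape": list(stack.shape),
    }
    sidecar_path(tiff_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return tiff_path


def read_stack(tiff_path, channel_map: dict[str, int] | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (or any C-first stack).

    Without a sidecar, ``channel_map`` (name → channel index) and a voxel
    size of 1 μm are assumed; the sidecar, when present, wins.
    """
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    side = sidecar_path(tiff_path)
    if side.exists():
        meta = json.loads(side.read_text())
        names = meta["channels"]
        voxel = tuple(meta["voxel_size_um"])
    elif channel_map is not None:
        names = [None] * data.shape[0]
        for name, idx in channel_map.items():
            names[idx] = name
        voxel = (1.0,) * (data.ndim - 1)
    else:
        raise ValueError(f"no sidecar {side} and no channel_map given")
    channels = {name: data[i] for i, name in enumerate(names)}
    return ImageStack(channels=channels, voxel_size=voxel)
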