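"""Readers and writers for the on-disk formats.

Conventions, stated once: pixel coordinates on disk are 0-based (row, col)
everywhere.  Region files are JSON; the canonical form is an object
``{"shape": [H, W], "regions": [{"coordinates": [[r, c], ...]}, ...]}`` but a
bare list of region objects (the community format) is accepted on read, with
the canvas shape inferred from the coordinates or passed explicitly.  Label
rasters are 16-bit TIFFs with 0 = background and k = neuron k-1 ... i.e.
mask index k stores label k+1.  Videos are multi-page grayscale TIFF stacks
or HDF5 files with a "video" dataset (T x H x W).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .evaluation import MaskSet, NeuronMask
from .preprocess import VideoStack

__all__ = [
    "read_video",
    "write_video",
    "read_regions",
    "write_regions",
    "read_label_image",
    "write_label_image",
    "write_image",
    "read_image",
    "load_config",
    "config_hash",
]


def read_video(path, normalize: bool = False) -> VideoStack:
    """Load a video from a multi-page TIFF or an HDF5 "video" dataset.

    Integer inputs are promoted to float losslessly; ``normalize`` divides by
    the dtype maximum so 8- and 16-bit renderings of one scene coincide.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "video" not in f:
                raise ValueError(f"{path} has no 'video' dataset")
            data = f["video"][...]
    else:
        data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a T x H x W stack, got shape {data.shape}")
    scale = np.iinfo(data.dtype).max if (normalize and np.issubdtype(data.dtype, np.integer)) else 1
    return VideoStack(data.astype(np.float64) / scale)


def write_video(video: VideoStack, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("video", data=video.frames)
    else:
        tifffile.imwrite(str(path), video.frames.astype(np.float32))


def write_image(image, path, bit_depth: int = 8) -> None:
    """Write a [0,1] image as scaled 8-bit (viewers) or raw float TIFF."""
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    path = Path(path)
    if bit_depth == 8:
        tifffile.imwrite(str(path), np.round(pixels * 255).astype(np.uint8))
    elif bit_depth == 32:
        tifffile.imwrite(str(path), pixels.astype(np.float32))
    else:
        raise ValueError("bit_depth must be 8 or 32")


def read_image(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    return data.astype(np.float64)


def write_regions(masks: MaskSet, path) -> None:
    payload = {
        "shape": list(masks.shape),
        "regions": [{"coordinates": [[int(r), int(c)] for r, c in sorted(m.pixels)]}
                    for m in masks],
    }
    Path(path).write_text(json.dumps(payload))


def read_regions(path, shape=None) -> MaskSet:
    """Read a regions JSON (canonical object or bare community list)."""
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict):
        regions = raw["regions"]
        shape = tuple(raw.get("shape")) if raw.get("shape") else shape
    else:
        regions = raw
    masks = []
    max_r = max_c = -1
    for i, region in enumerate(regions):
        coords = region["coordinates"]
        if not coords:
            raise ValueError(f"region {i} has no coordinates")
        masks.append(NeuronMask(frozenset((int(r), int(c)) for r, c in coords)))
        rs, cs = zip(*coords)
        max_r, max_c = max(max_r, max(rs)), max(max_c, max(cs))
    if shape is None:
        shape = (max_r + 1, max_c + 1)
    try:
        return MaskSet(masks, tuple(shape))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_label_image(masks: MaskSet, path) -> None:
    tifffile.imwrite(str(path), masks.to_label_image())


def read_label_image(path) -> MaskSet:
    return MaskSet.from_label_image(tifffile.imread(str(path)))


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
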