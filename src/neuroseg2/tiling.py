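"""Tiled inference for fields of view larger than the network input.

A mesoscopic image (e.g. 1,792 x 1,682 px) is covered by a grid of
network-sized tiles — ceil(H/stride) x ceil(W/stride) of them with
stride = tile_size - overlap, border tiles clipped to the image — predicted
tile by tile, and the per-tile detections are translated back to global
coordinates.  Duplicates of neurons seen by more than one overlapping tile
(IoU at or above ``merge_iou``) are merged by pixel union, keeping the
higher score.  With the default 100 px tiles and no overlap the 1,792 x
1,682 canvas yields exactly 17 x 18 = 306 tiles; an overlap of about one
soma diameter (20 px) is recommended in practice so border-straddling
neurons are seen whole by at least one tile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import MaskSet, NeuronMask, iou
from .network import Detection

__all__ = ["TileGrid", "make_grid", "merge", "predict_tiled"]

DEFAULT_TILE = 100
DEFAULT_MERGE_IOU = 0.5


@dataclass
class TileGrid:
    image_shape: tuple           # (H, W)
    tile_size: tuple             # (h, w)
    overlap: int
    offsets: list                # row-major (row0, col0) tile origins

    def __len__(self):
        return len(self.offsets)

    def tile_bounds(self, index: int) -> tuple:
        """(r0, c0, r1, c1) of a tile, clipped to the image."""
        r0, c0 = self.offsets[index]
        h, w = self.image_shape
        th, tw = self.tile_size
        return r0, c0, min(r0 + th, h), min(c0 + tw, w)

    def extract(self, image: np.ndarray, index: int) -> np.ndarray:
        r0, c0, r1, c1 = self.tile_bounds(index)
        return image[r0:r1, c0:c1]


def make_grid(height: int, width: int, tile_size=DEFAULT_TILE, overlap: int = 0) -> TileGrid:
    """Build the covering tile grid for an H x W image."""
    th, tw = (tile_size, tile_size) if np.isscalar(tile_size) else tile_size
    if overlap < 0 or overlap >= min(th, tw):
        raise ValueError(f"overlap must satisfy 0 <= overlap < tile size, got {overlap}")
    sr, sc = th - overlap, tw - overlap
    n_rows = -(-height // sr)   # ceil division
    n_cols = -(-width // sc)
    offsets = [(i * sr, j * sc) for i in range(n_rows) for j in range(n_cols)]
    return TileGrid((height, width), (th, tw), overlap, offsets)


def merge(per_tile_detections: list, grid: TileGrid,
          merge_iou: float = DEFAULT_MERGE_IOU) -> tuple:
    """Recombine per-tile detections into a full-field MaskSet.

    ``per_tile_detections[i]`` is the detection list for tile i, in tile-local
    coordinates.  Returns (MaskSet, scores) ordered by descending score.
    """
    h, w = grid.image_shape
    translated = []  # (score, pixel set)
    for index, detections in enumerate(per_tile_detections):
        r0, c0, r1, c1 = grid.tile_bounds(index)
        for det in detections:
            rows, cols = np.nonzero(det.mask)
            if rows.size and (rows.max() >= r1 - r0 or cols.max() >= c1 - c0):
                raise ValueError(f"detection exceeds the bounds of tile {index}")
            pixels = frozenset(zip((rows + r0).tolist(), (cols + c0).tolist()))
            if pixels:
                translated.append((float(det.score), pixels))
    translated.sort(key=lambda t: -t[0])

    kept: list = []   # [score, set]
    for score, pixels in translated:
        mask = NeuronMask(pixels)
        merged = False
        for entry in kept:
            if iou(NeuronMask(entry[1]), mask) >= merge_iou:
                entry[1] = entry[1] | pixels        # pixel union
                entry[0] = max(entry[0], score)     # keep the higher score
                merged = True
                break
        if not merged:
            kept.append([score, set(pixels)])
    masks = MaskSet([NeuronMask(frozenset(p)) for _, p in kept], (h, w))
    return masks, [s for s, _ in kept]


def predict_tiled(model, image: np.ndarray, tile_size=DEFAULT_TILE, overlap: int = 20,
                  merge_iou: float = DEFAULT_MERGE_IOU) -> tuple:
    """Split, predict per tile, and merge: the mesoscopic inference path."""
    image = np.asarray(getattr(image, "pixels", image), dtype=float)
    grid = make_grid(*image.shape, tile_size=tile_size, overlap=overlap)
    per_tile = [model.predict(grid.extract(image, i)) for i in range(len(grid))]
    return merge(per_tile, grid, merge_iou)
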