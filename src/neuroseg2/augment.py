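"""Training-time augmentation applied jointly to an image and its masks.

The menu has five operations: horizontal flip, vertical flip, rotation by a
multiple of 90 degrees, isotropic scaling in [0.8, 1.5], and additive
Gaussian noise with sigma drawn from [0.0, 5.0] on the 8-bit intensity
scale.  For each call a count k is drawn uniformly from {0..max_ops}, k
distinct operations are sampled without replacement, and they are applied in
a fixed canonical order (geometric first, noise last) so runs are
reproducible.  Geometric operations transform image and masks identically;
noise touches the image only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import rescale as _sk_rescale

from .evaluation import MaskSet, NeuronMask

logger = logging.getLogger(__name__)

__all__ = ["AugmentConfig", "augment", "apply_op", "OP_ORDER"]

OP_ORDER = ("hflip", "vflip", "rotate", "scale", "noise")


@dataclass
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotations: tuple = (90, 180, 270)
    scale_range: tuple = (0.8, 1.5)
    noise_sigma_range: tuple = (0.0, 5.0)   # sigma on the 0-255 intensity scale
    max_ops: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.max_ops <= 5:
            raise ValueError("max_ops must lie in 0..5")
        if not set(self.rotations) <= {90, 180, 270}:
            raise ValueError("rotations must be multiples of 90 in {90, 180, 270}")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must be positive and ordered")


def _masks_to_stack(masks: MaskSet) -> np.ndarray:
    return np.stack([m.to_array(masks.shape) for m in masks]) if len(masks) else \
        np.zeros((0, *masks.shape), dtype=bool)


def _stack_to_masks(stack: np.ndarray, shape) -> MaskSet:
    out = []
    for i, arr in enumerate(stack):
        if arr.any():
            out.append(NeuronMask.from_array(arr))
        else:
            logger.info("mask %d emptied by augmentation; dropped", i)
    return MaskSet(out, shape)


def _rescale_to_canvas(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Resample by ``factor`` then centre-crop / zero-pad back to the canvas."""
    h, w = arr.shape
    scaled = _sk_rescale(arr.astype(float), factor, order=order, anti_aliasing=False,
                         preserve_range=True)
    sh, sw = scaled.shape
    out = np.zeros_like(arr, dtype=scaled.dtype)
    if sh >= h:
        r0, c0 = (sh - h) // 2, (sw - w) // 2
        out = scaled[r0 : r0 + h, c0 : c0 + w]
    else:
        r0, c0 = (h - sh) // 2, (w - sw) // 2
        out[r0 : r0 + sh, c0 : c0 + sw] = scaled
    return out


def apply_op(name: str, image: np.ndarray, mask_stack: np.ndarray, params: dict):
    """Apply one named operation to the image and the (N,H,W) mask stack."""
    if name == "hflip":
        return image[:, ::-1].copy(), mask_stack[:, :, ::-1].copy()
    if name == "vflip":
        return image[::-1].copy(), mask_stack[:, ::-1].copy()
    if name == "rotate":
        k = params["angle"] // 90
        return np.rot90(image, k).copy(), np.rot90(mask_stack, k, axes=(1, 2)).copy()
    if name == "scale":
        factor = params["factor"]
        img = _rescale_to_canvas(image, factor, order=1)
        masks = np.stack([
            _rescale_to_canvas(m.astype(float), factor, order=0) > 0.5 for m in mask_stack
        ]) if len(mask_stack) else mask_stack
        return img, masks
    if name == "noise":
        sigma = params["sigma"]
        noisy = image + params["rng"].normal(0.0, sigma, size=image.shape) / 255.0
        return noisy, mask_stack
    raise ValueError(f"unknown augmentation op {name!r}")


def augment(image: np.ndarray, masks: MaskSet, cfg: AugmentConfig | None = None,
            rng: np.random.Generator | None = None, force_ops: list | None = None):
    """Randomly augment an (image, MaskSet) pair.

    ``force_ops`` bypasses the random menu and applies exactly the named
    operations (in canonical order) — useful for deterministic testing.
    Returns (image, MaskSet); rotations require a square canvas.
    """
    cfg = cfg or AugmentConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(masks.shape):
        raise ValueError(f"image shape {image.shape} differs from mask canvas {masks.shape}")

    if force_ops is None:
        k = int(rng.integers(0, cfg.max_ops + 1))
        chosen = set(rng.choice(len(OP_ORDER), size=k, replace=False).tolist())
        ops = [OP_ORDER[i] for i in sorted(chosen)]
    else:
        ops = [op for op in OP_ORDER if op in force_ops]

    params = {
        "angle": int(rng.choice(cfg.rotations)),
        "factor": float(rng.uniform(*cfg.scale_range)),
        "sigma": float(rng.uniform(*cfg.noise_sigma_range)),
        "rng": rng,
    }
    stack = _masks_to_stack(masks)
    for op in ops:
        if op == "rotate" and image.shape[0] != image.shape[1]:
            raise ValueError("rotation requires a square canvas")
        image, stack = apply_op(op, image, stack, params)
    return image, _stack_to_masks(stack, masks.shape)
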