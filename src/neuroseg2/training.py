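"""Staged training schedules and cross-validation protocols.

Training runs in stages that freeze or thaw parts of the network.  The two
reference schedules are:

* hybrid: 200 epochs in three stages — 50 epochs at lr 1e-3 with only the
  head branches trainable, 100 epochs at 2e-4 and 50 at 1e-4 with the whole
  network thawed; 500 steps per epoch, batch size 2.
* neurofinder: 150 epochs in two stages — 20 head-only epochs then 130
  whole-network epochs, both at lr 1e-3; 50 steps per epoch, batch size 2.

The "head" scope covers the classification/regression and mask branches;
the RPN is excluded.  The optimizer is SGD with momentum 0.9 and weight
decay 1e-4 (the convention of the Mask R-CNN family; only the learning
rates are prescribed).

Two cross-validation protocols are provided: two-round hybrid (the groups
are halved; each half is tested by a model trained on the other half's
training data, so every group is tested exactly once) and N-round single
(one model per group, trained on that group's training images and tested on
its own test items).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, augment
from .evaluation import MaskSet, evaluate_masks
from .layers import SGD
from .network import NeuroSegModel

__all__ = [
    "TrainStage",
    "Schedule",
    "DatasetGroup",
    "hybrid_schedule",
    "neurofinder_schedule",
    "train",
    "cross_validate",
    "masks_to_targets",
]


@dataclass
class TrainStage:
    scope: str               # heads_only | all_layers
    epochs: int
    learning_rate: float
    steps_per_epoch: int = 500
    batch_size: int = 2

    def __post_init__(self):
        if self.scope not in ("heads_only", "all_layers"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if min(self.epochs, self.steps_per_epoch, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("stage fields must be positive")


@dataclass
class Schedule:
    stages: list
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not self.stages:
            raise ValueError("a schedule needs at least one stage")

    @property
    def total_epochs(self) -> int:
        return sum(s.epochs for s in self.stages)


def hybrid_schedule() -> Schedule:
    """Three-stage 200-epoch schedule used with the hybrid (multi-lab) data."""
    return Schedule([
        TrainStage("heads_only", 50, 1e-3, steps_per_epoch=500, batch_size=2),
        TrainStage("all_layers", 100, 2e-4, steps_per_epoch=500, batch_size=2),
        TrainStage("all_layers", 50, 1e-4, steps_per_epoch=500, batch_size=2),
    ])


def neurofinder_schedule() -> Schedule:
    """Two-stage 150-epoch schedule used for the benchmark cross-validation."""
    return Schedule([
        TrainStage("heads_only", 20, 1e-3, steps_per_epoch=50, batch_size=2),
        TrainStage("all_layers", 130, 1e-3, steps_per_epoch=50, batch_size=2),
    ])


def masks_to_targets(masks: MaskSet) -> dict:
    """Convert a MaskSet into the box/mask-raster targets the loss expects."""
    boxes, rasters = [], []
    for m in masks:
        arr = m.to_array(masks.shape)
        rows, cols = np.nonzero(arr)
        boxes.append([rows.min(), cols.min(), rows.max() + 1, cols.max() + 1])
        rasters.append(arr)
    return {"boxes": np.asarray(boxes, dtype=float),
            "masks": np.asarray(rasters, dtype=bool)}


def _prepare(image, masks: MaskSet, input_size: int):
    """Zero-pad an image/masks pair to the network canvas."""
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    h, w = pixels.shape
    if h > input_size or w > input_size:
        raise ValueError(f"training image {pixels.shape} exceeds input size {input_size}")
    canvas = np.zeros((input_size, input_size))
    canvas[:h, :w] = pixels
    padded_masks = MaskSet(list(masks.masks), (input_size, input_size))
    return canvas, padded_masks


def train(model: NeuroSegModel, dataset: list, schedule: Schedule,
          augment_cfg: AugmentConfig | None = None, callback=None):
    """Run the staged schedule over a dataset of (image, MaskSet) pairs.

    Returns (model, history) where history is a list of per-epoch mean total
    losses (length = sum of stage epochs).  Deterministic given the schedule
    seed.  Non-finite losses abort with stage/step context.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(schedule.seed)
    size = model.cfg.input_size
    prepared = [_prepare(img, masks, size) for img, masks in dataset]
    history = []
    for stage_idx, stage in enumerate(schedule.stages):
        params = model.trainable_parameters(stage.scope)
        opt = SGD(params, lr=stage.learning_rate, momentum=schedule.momentum,
                  weight_decay=schedule.weight_decay)
        for epoch in range(stage.epochs):
            losses = []
            for step in range(stage.steps_per_epoch):
                opt.zero_grad()
                batch_total = None
                for _ in range(stage.batch_size):
                    idx = int(rng.integers(len(prepared)))
                    image, masks = prepared[idx]
                    if augment_cfg is not None:
                        image, masks = augment(image, masks, augment_cfg, rng=rng)
                        if len(masks) == 0:
                            image, masks = prepared[idx]
                    target = masks_to_targets(masks)
                    total, _components = model.loss(image, target, rng=rng)
                    if not np.isfinite(total.data):
                        raise FloatingPointError(
                            f"non-finite loss at stage {stage_idx}, epoch {epoch}, step {step}")
                    batch_total = total if batch_total is None else batch_total + total
                batch_total = batch_total * (1.0 / stage.batch_size)
                batch_total.backward()
                opt.step()
                losses.append(float(batch_total.data))
            history.append(float(np.mean(losses)))
            if callback is not None:
                callback(stage_idx, epoch, history[-1])
    return model, history


@dataclass
class DatasetGroup:
    """One cross-validation group: training items and held-out test items,
    each a list of (image, MaskSet) pairs."""

    name: str
    train_items: list
    test_items: list


def _evaluate_items(model: NeuroSegModel, items: list):
    reports = []
    for image, gt in items:
        detections = model.predict(image)
        shape = tuple(gt.shape)
        from .evaluation import NeuronMask  # local import to avoid cycle noise
        det_masks = MaskSet([NeuronMask.from_array(d.mask) for d in detections
                             if d.mask.any()], shape)
        reports.append(evaluate_masks(gt, det_masks))
    return reports


def cross_validate(groups: list, protocol: str, model_factory, schedule: Schedule,
                   augment_cfg: AugmentConfig | None = None) -> dict:
    """Run a cross-validation protocol over DatasetGroups.

    ``model_factory()`` must return a fresh model.  Returns {group name:
    list of MetricsReports for its test items}; every group is tested
    exactly once in both protocols.
    """
    if len(groups) < 2:
        raise ValueError("cross-validation needs at least 2 groups")
    results = {}
    if protocol == "two_round_hybrid":
        if len(groups) % 2:
            raise ValueError("two-round hybrid cross-validation needs an even group count")
        half = len(groups) // 2
        halves = [groups[:half], groups[half:]]
        for tested, source in ((0, 1), (1, 0)):
            train_data = [item for g in halves[source] for item in g.train_items]
            model, _ = train(model_factory(), train_data, schedule, augment_cfg)
            for g in halves[tested]:
                results[g.name] = _evaluate_items(model, g.test_items)
    elif protocol == "ten_round_single":
        for g in groups:
            model, _ = train(model_factory(), g.train_items, schedule, augment_cfg)
            results[g.name] = _evaluate_items(model, g.test_items)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return results
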