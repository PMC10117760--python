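"""Shared fixtures: small synthetic scenes and a session-scoped overfit model.

The toy model configuration keeps every component of the architecture but
shrinks channel widths and the input canvas so CPU training is feasible;
the expensive overfit training runs once per session and is reused by the
prediction, tiling and end-to-end tests.
"""

import numpy as np
import pytest

import neuroseg2 as ns
from neuroseg2.evaluation import MaskSet, NeuronMask
from neuroseg2.training import Schedule, TrainStage, train


TOY_SIZE = 128


def toy_model_config(**overrides) -> ns.ModelConfig:
    base = dict(
        backbone_depth=10,
        base_channels=8,
        fpn_channels=16,
        head_dim=64,
        input_size=TOY_SIZE,
        anchor_scales=(8, 16, 24, 32, 48),
        rpn_pre_nms=300,
        rpn_post_nms=80,
    )
    base.update(overrides)
    return ns.ModelConfig(**base)


@pytest.fixture(scope="session")
def toy_cfg() -> ns.ModelConfig:
    return toy_model_config()


@pytest.fixture(scope="session")
def toy_scene():
    """A small, clearly resolvable scene: 6 separated bright somata."""
    cfg = ns.SyntheticConfig(image_size=(TOY_SIZE, TOY_SIZE), n_frames=120, n_neurons=6,
                             overlap_pairs=0, noise_sigma=1.0, seed=1)
    video, gt = ns.generate(cfg)
    fused = ns.fuse(ns.average_projection(video), ns.correlation_map(video))
    return {"video": video, "gt": gt, "image": fused.pixels}


def hflip_maskset(masks: MaskSet) -> MaskSet:
    h, w = masks.shape
    return MaskSet(
        [NeuronMask.from_array(m.to_array((h, w))[:, ::-1]) for m in masks], (h, w)
    )


@pytest.fixture(scope="session")
def overfit_model(toy_scene, toy_cfg):
    """Toy model overfit on one scene in both horizontal orientations."""
    model = ns.build_model(toy_cfg, seed=0)
    img = toy_scene["image"]
    masks = toy_scene["gt"].masks
    flip_img = img[:, ::-1].copy()
    schedule = Schedule([
        TrainStage("all_layers", 8, 1e-2, steps_per_epoch=50, batch_size=1),
        TrainStage("all_layers", 6, 2e-3, steps_per_epoch=50, batch_size=1),
    ], seed=0)
    model, history = train(model, [(img, masks), (flip_img, hflip_maskset(masks))], schedule)
    return {"model": model, "history": history}


@pytest.fixture
def square_masks():
    """Two simple rectangular masks on a 32x32 canvas."""
    canvas = (32, 32)
    a = np.zeros(canvas, dtype=bool)
    a[4:10, 4:10] = True
    b = np.zeros(canvas, dtype=bool)
    b[20:28, 18:26] = True
    return MaskSet([NeuronMask.from_array(a), NeuronMask.from_array(b)], canvas)
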