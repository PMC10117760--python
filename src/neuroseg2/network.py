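"""The segmentation network: a Mask R-CNN-style two-stage detector with
channel attention and an augmented feature pyramid.

Architecture, configurable per ablation arm:

* ResNet-style backbone emitting C2..C5, plus one extra down-sampling stage
  (C6) when ``path_augmentation`` is on — five feature levels instead of four.
* Feature pyramid (FPN): 1x1 lateral projections, optionally gated by an
  efficient-channel-attention (ECA) module on every lateral connection, fused
  top-down with nearest-neighbour upsampling.  The up-path fusion mode is
  configurable ('add' elementwise, or 'concat' followed by a CSP layer).
* FPN+: a second, bottom-up path fed by lateral connections from the FPN
  outputs, producing feature maps Y2..Y6; the down-path fusion mode is again
  'add' or 'concat'+CSP.  The reference configuration uses add for
  up-sampling and concat for down-sampling.
* Region proposal network shared across levels, ROI-Align feature cropping,
  and parallel classification/box-regression and mask heads.

The loss combines classification, box regression and mask terms.  All boxes
are (r0, c0, r1, c1), 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .layers import BasicBlock, CBAM, Conv2d, CSPLayer, ECA, Linear, Module, Sequential, upsample2x

__all__ = [
    "ModelConfig",
    "Detection",
    "NeuroSegModel",
    "build_model",
    "eca",
    "fuse_features",
    "num_lateral_connections",
]

_DEPTH_BLOCKS = {10: [1, 1, 1, 1], 18: [2, 2, 2, 2], 34: [3, 4, 6, 3]}


@dataclass
class ModelConfig:
    """Architecture switches; every ablation arm is reachable from here."""

    backbone_depth: int = 18
    base_channels: int = 64
    fpn_channels: int = 64
    head_dim: int = 256
    attention: str = "eca"              # none | eca | cbam
    eca_kernel: int = 3
    fpn_plus: bool = True
    path_augmentation: bool = True      # extra down-sampling after C5 -> C6
    fusion_up: str = "add"
    fusion_down: str = "concat"
    csp_depth: int = 1
    anchor_scales: tuple = (8, 16, 32, 64, 128)
    anchor_ratios: tuple = (1.0,)
    max_instances: int = 500
    score_threshold: float = 0.5
    mask_threshold: float = 0.5
    input_size: int = 512
    roi_size: int = 7
    mask_roi_size: int = 14
    rpn_pre_nms: int = 600
    rpn_post_nms: int = 150
    rpn_nms_iou: float = 0.7
    detection_nms_iou: float = 0.5

    def __post_init__(self):
        if self.backbone_depth not in _DEPTH_BLOCKS:
            raise ValueError(f"backbone_depth must be one of {sorted(_DEPTH_BLOCKS)}")
        if self.attention not in ("none", "eca", "cbam"):
            raise ValueError(f"unknown attention mode {self.attention!r}")
        if self.eca_kernel < 1 or self.eca_kernel % 2 == 0:
            raise ValueError("eca_kernel must be a positive odd integer")
        for mode in (self.fusion_up, self.fusion_down):
            if mode not in ("add", "concat"):
                raise ValueError(f"fusion mode must be 'add' or 'concat', got {mode!r}")
        if list(self.anchor_scales) != sorted(self.anchor_scales):
            raise ValueError("anchor_scales must be sorted ascending")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")
        if self.input_size % 64 != 0:
            raise ValueError("input_size must be a multiple of 64 (the deepest stride)")
        if len(self.anchor_scales) < self.n_levels:
            raise ValueError("need one anchor scale per pyramid level")

    @property
    def n_levels(self) -> int:
        return 5 if self.path_augmentation else 4


@dataclass
class Detection:
    """One predicted neuron: full-canvas binary mask, box and confidence."""

    mask: np.ndarray
    box: tuple
    score: float

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("detection mask is empty")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def num_lateral_connections(cfg: ModelConfig) -> int:
    """Lateral connections carrying an attention module: one per FPN level
    plus, when FPN+ is enabled, one per bottom-up fusion."""
    n = cfg.n_levels
    return n + (n - 1 if cfg.fpn_plus else 0)


def eca(feature, kernel: int, weights=None):
    """Functional ECA: gate the channels of an NCHW tensor/array.

    ``weights`` optionally fixes the 1-D convolution weights (length
    ``kernel``); by default the centre-tap identity initialisation is used.
    """
    module = ECA(kernel)
    if weights is not None:
        module.weight.data[...] = np.asarray(weights, dtype=np.float32)
    x = feature if isinstance(feature, Tensor) else Tensor(feature)
    return module(x)


def fuse_features(a: Tensor, b: Tensor, mode: str, names=("a", "b")) -> Tensor:
    """Fuse two feature maps: 'add' (channels preserved, must match) or
    'concat' (channels stacked; callers follow with a CSP layer)."""
    if a.shape[2:] != b.shape[2:]:
        raise ValueError(f"spatial shapes differ between {names[0]} {a.shape} and {names[1]} {b.shape}")
    if mode == "add":
        if a.shape[1] != b.shape[1]:
            raise ValueError(f"'add' fusion needs equal channels: {names[0]} has {a.shape[1]}, "
                             f"{names[1]} has {b.shape[1]}")
        return a + b
    if mode == "concat":
        return concat([a, b], axis=1)
    raise ValueError(f"unknown fusion mode {mode!r}")


# --------------------------------------------------------------------------
# numpy box utilities (proposal plumbing; gradients never flow through boxes)
# --------------------------------------------------------------------------

def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between two (N,4) / (M,4) box arrays."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.prod(np.clip(br - tl, 0, None), axis=2)
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    return inter / (area_a[:, None] + area_b[None, :] - inter + 1e-9)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = box_iou_matrix(boxes[i : i + 1], boxes[order[1:]])[0]
        order = order[1:][ious < iou_threshold]
    return np.array(keep, dtype=int)


def encode_deltas(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    ah, aw = anchors[:, 2] - anchors[:, 0], anchors[:, 3] - anchors[:, 1]
    ac = (anchors[:, :2] + anchors[:, 2:]) / 2
    gh, gw = gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]
    gc = (gt[:, :2] + gt[:, 2:]) / 2
    return np.stack([
        (gc[:, 0] - ac[:, 0]) / ah, (gc[:, 1] - ac[:, 1]) / aw,
        np.log(gh / ah), np.log(gw / aw),
    ], axis=1)


def decode_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    ah, aw = anchors[:, 2] - anchors[:, 0], anchors[:, 3] - anchors[:, 1]
    ac = (anchors[:, :2] + anchors[:, 2:]) / 2
    cy = ac[:, 0] + deltas[:, 0] * ah
    cx = ac[:, 1] + deltas[:, 1] * aw
    h = ah * np.exp(np.clip(deltas[:, 2], -4, 4))
    w = aw * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cy - h / 2, cx - w / 2, cy + h / 2, cx + w / 2], axis=1)


# --------------------------------------------------------------------------
# differentiable helpers
# --------------------------------------------------------------------------

def roi_align(feature: Tensor, boxes: np.ndarray, out_size: int, stride: float) -> Tensor:
    """Crop each box from a (1,C,H,W) feature map to (R,C,P,P) by sampling one
    bilinear point per output bin.  Box coordinates are constants."""
    _, c, h, w = feature.shape
    r = len(boxes)
    p = out_size
    bins = (np.arange(p) + 0.5) / p
    grid_y = (boxes[:, 0, None] + bins * (boxes[:, 2] - boxes[:, 0])[:, None]) / stride - 0.5
    grid_x = (boxes[:, 1, None] + bins * (boxes[:, 3] - boxes[:, 1])[:, None]) / stride - 0.5
    gy = np.clip(grid_y, 0, h - 1)[:, :, None].repeat(p, axis=2)  # (R,P,P)
    gx = np.clip(grid_x, 0, w - 1)[:, None, :].repeat(p, axis=1)
    y0 = np.floor(gy).astype(int)
    x0 = np.floor(gx).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = gy - y0
    wx = gx - x0
    flat = feature.reshape(c, h * w)
    out = None
    for yy, xx, wgt in (
        (y0, x0, (1 - wy) * (1 - wx)),
        (y0, x1, (1 - wy) * wx),
        (y1, x0, wy * (1 - wx)),
        (y1, x1, wy * wx),
    ):
        idx = (yy * w + xx).reshape(-1)
        term = flat[:, idx] * wgt.reshape(1, -1)
        out = term if out is None else out + term
    return out.reshape(c, r, p, p).transpose(1, 0, 2, 3)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    t = np.asarray(targets, dtype=np.float32)
    absx = logits.relu() + (-logits).relu()
    loss = logits.relu() - logits * t + ((-absx).exp() + 1.0).log()
    return loss.mean()

def smooth_l1(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Mean smooth-L1 (Huber, delta=1) between predictions and constants."""
    t = np.asarray(targets, dtype=np.float32)
    d = pred - t
    quad = (np.abs(d.data) < 1).astype(np.float32)
    sign = np.sign(d.data).astype(np.float32)
    loss = d * d * (0.5 * quad) + d * (sign * (1 - quad)) - Tensor(0.5 * (1 - quad))
    return loss.mean()


# --------------------------------------------------------------------------
# sub-networks
# --------------------------------------------------------------------------

class Backbone(Module):
    """ResNet-style feature extractor; emits C2..C5 (strides 4..32) and, with
    path augmentation, an extra down-sampled C6 (stride 64)."""

    def __init__(self, cfg: ModelConfig, rng):
        b = cfg.base_channels
        blocks = _DEPTH_BLOCKS[cfg.backbone_depth]
        self.stem = Conv2d(1, b, 3, rng, stride=2)
        widths = [b, 2 * b, 4 * b, 8 * b]
        self.stages = []
        cin = b
        for n_blocks, width in zip(blocks, widths):
            stage = [BasicBlock(cin, width, rng, stride=2)]
            stage += [BasicBlock(width, width, rng) for _ in range(n_blocks - 1)]
            self.stages.append(Sequential(*stage))
            cin = width
        self.extra_down = Conv2d(cin, cin, 3, rng, stride=2) if cfg.path_augmentation else None
        self.out_channels = widths + ([cin] if cfg.path_augmentation else [])

    def forward(self, x: Tensor) -> list:
        x = self.stem(x).relu()
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        if self.extra_down is not None:
            feats.append(self.extra_down(x).relu())
        return feats


def _make_attention(cfg: ModelConfig, channels: int, rng):
    if cfg.attention == "eca":
        return ECA(cfg.eca_kernel)
    if cfg.attention == "cbam":
        return CBAM(channels, rng)
    return None


class FPN(Module):
    """Top-down pyramid with attention-gated lateral connections."""

    def __init__(self, cfg: ModelConfig, in_channels: list, rng):
        f = cfg.fpn_channels
        self.cfg = cfg
        self.laterals = [Conv2d(c, f, 1, rng) for c in in_channels]
        self.attentions = [_make_attention(cfg, f, rng) for _ in in_channels]
        self.fusion_csp = (
            [CSPLayer(2 * f, f, rng, cfg.csp_depth) for _ in in_channels[:-1]]
            if cfg.fusion_up == "concat" else None
        )
        self.outputs = [Conv2d(f, f, 3, rng) for _ in in_channels]

    def forward(self, feats: list) -> list:
        lats = []
        for feat, lat, att in zip(feats, self.laterals, self.attentions):
            x = lat(feat)
            if att is not None:
                x = att(x)
            lats.append(x)
        pyramid = [None] * len(lats)
        pyramid[-1] = lats[-1]
        for i in range(len(lats) - 2, -1, -1):
            up = upsample2x(pyramid[i + 1])
            fused = fuse_features(lats[i], up, self.cfg.fusion_up, (f"P{i+2}", f"P{i+3}"))
            if self.cfg.fusion_up == "concat":
                fused = self.fusion_csp[i](fused)
            pyramid[i] = fused
        return [conv(p) for conv, p in zip(self.outputs, pyramid)]


class FPNPlus(Module):
    """Bottom-up augmentation path: Y2 = P2; each further level fuses a
    stride-2 down-sampling of the previous Y with a lateral (attention-gated)
    projection of the corresponding P, yielding Y2..Y6."""

    def __init__(self, cfg: ModelConfig, n_levels: int, rng):
        f = cfg.fpn_channels
        self.cfg = cfg
        self.downs = [Conv2d(f, f, 3, rng, stride=2) for _ in range(n_levels - 1)]
        self.laterals = [Conv2d(f, f, 1, rng) for _ in range(n_levels - 1)]
        self.attentions = [_make_attention(cfg, f, rng) for _ in range(n_levels - 1)]
        self.fusion_csp = (
            [CSPLayer(2 * f, f, rng, cfg.csp_depth) for _ in range(n_levels - 1)]
            if cfg.fusion_down == "concat" else None
        )

    def forward(self, pyramid: list) -> list:
        ys = [pyramid[0]]
        for i in range(len(pyramid) - 1):
            down = self.downs[i](ys[-1]).relu()
            lat = self.laterals[i](pyramid[i + 1])
            if self.attentions[i] is not None:
                lat = self.attentions[i](lat)
            fused = fuse_features(down, lat, self.cfg.fusion_down, (f"Y{i+2}->down", f"P{i+3}"))
            if self.cfg.fusion_down == "concat":
                fused = self.fusion_csp[i](fused)
            ys.append(fused)
        return ys


class RPN(Module):
    def __init__(self, cfg: ModelConfig, rng):
        f = cfg.fpn_channels
        a = len(cfg.anchor_ratios)
        self.shared = Conv2d(f, f, 3, rng)
        self.objectness = Conv2d(f, a, 1, rng)
        self.deltas = Conv2d(f, 4 * a, 1, rng)

    def forward(self, feats: list):
        obj, dlt = [], []
        for feat in feats:
            x = self.shared(feat).relu()
            obj.append(self.objectness(x))
            dlt.append(self.deltas(x))
        return obj, dlt


class BoxHead(Module):
    def __init__(self, cfg: ModelConfig, rng):
        f = cfg.fpn_channels
        self.fc1 = Linear(f * cfg.roi_size**2, cfg.head_dim, rng)
        self.fc2 = Linear(cfg.head_dim, cfg.head_dim, rng)
        self.cls = Linear(cfg.head_dim, 1, rng)
        self.reg = Linear(cfg.head_dim, 4, rng)

    def forward(self, rois: Tensor):
        r = rois.shape[0]
        x = self.fc2(self.fc1(rois.reshape(r, -1)).relu()).relu()
        return self.cls(x), self.reg(x)


class MaskHead(Module):
    def __init__(self, cfg: ModelConfig, rng):
        f = cfg.fpn_channels
        self.conv1 = Conv2d(f, f, 3, rng)
        self.conv2 = Conv2d(f, f, 3, rng)
        self.conv3 = Conv2d(f, f, 3, rng)
        self.logit = Conv2d(f, 1, 1, rng)

    def forward(self, rois: Tensor) -> Tensor:
        x = self.conv2(self.conv1(rois).relu()).relu()
        x = upsample2x(x)
        return self.logit(self.conv3(x).relu())


# --------------------------------------------------------------------------
# the full model
# --------------------------------------------------------------------------

class NeuroSegModel(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = Backbone(cfg, rng)
        self.fpn = FPN(cfg, self.backbone.out_channels, rng)
        self.fpn_plus = FPNPlus(cfg, cfg.n_levels, rng) if cfg.fpn_plus else None
        self.rpn = RPN(cfg, rng)
        self.box_head = BoxHead(cfg, rng)
        self.mask_head = MaskHead(cfg, rng)
        self.strides = [4 * 2**i for i in range(cfg.n_levels)]

    # -- plumbing ----------------------------------------------------------
    def parameter_groups(self) -> dict:
        groups = {
            "backbone": self.backbone.parameters(),
            "fpn": self.fpn.parameters() + (self.fpn_plus.parameters() if self.fpn_plus else []),
            "rpn": self.rpn.parameters(),
            "heads": self.box_head.parameters() + self.mask_head.parameters(),
        }
        return groups

    def trainable_parameters(self, scope: str = "all_layers") -> list:
        groups = self.parameter_groups()
        if scope == "all_layers":
            return [p for ps in groups.values() for p in ps]
        if scope == "heads_only":
            # the classification/regression and mask branches; RPN excluded
            return groups["heads"]
        raise ValueError(f"unknown scope {scope!r}")

    def feature_names(self) -> list:
        prefix = "Y" if self.cfg.fpn_plus else "P"
        return [f"{prefix}{i+2}" for i in range(self.cfg.n_levels)]

    def pyramid(self, image: np.ndarray) -> list:
        x = Tensor(np.asarray(image, dtype=np.float32).reshape(1, 1, *image.shape))
        feats = self.fpn(self.backbone(x))
        if self.fpn_plus is not None:
            feats = self.fpn_plus(feats)
        return feats

    def anchors_for(self, level: int, shape) -> np.ndarray:
        stride = self.strides[level]
        scale = self.cfg.anchor_scales[level]
        h, w = shape
        cy = (np.arange(h) + 0.5) * stride
        cx = (np.arange(w) + 0.5) * stride
        boxes = []
        for ratio in self.cfg.anchor_ratios:
            ah = scale * np.sqrt(ratio)
            aw = scale / np.sqrt(ratio)
            grid = np.stack(np.meshgrid(cy, cx, indexing="ij"), axis=-1).reshape(-1, 2)
            boxes.append(np.concatenate([grid - [ah / 2, aw / 2], grid + [ah / 2, aw / 2]], axis=1))
        return np.concatenate(boxes, axis=0)

    def _proposals(self, obj, dlt, training: bool):
        """Decode RPN outputs into scored, NMS-filtered proposal boxes."""
        size = self.cfg.input_size
        all_boxes, all_scores = [], []
        for level, (o, d) in enumerate(zip(obj, dlt)):
            h, w = o.shape[2], o.shape[3]
            a = len(self.cfg.anchor_ratios)
            scores = o.data.transpose(0, 2, 3, 1).reshape(-1)
            deltas = d.data.transpose(0, 2, 3, 1).reshape(-1, 4)
            anchors = self.anchors_for(level, (h, w))
            # anchors_for stacks ratios outermost; rebuild in matching order
            anchors = anchors.reshape(a, h * w, 4).transpose(1, 0, 2).reshape(-1, 4)
            keep = np.argsort(-scores, kind="stable")[: self.cfg.rpn_pre_nms]
            boxes = decode_deltas(anchors[keep], deltas[keep])
            boxes = np.clip(boxes, 0, size)
            valid = (boxes[:, 2] > boxes[:, 0] + 1) & (boxes[:, 3] > boxes[:, 1] + 1)
            all_boxes.append(boxes[valid])
            all_scores.append(scores[keep][valid])
        boxes = np.concatenate(all_boxes, axis=0)
        scores = np.concatenate(all_scores, axis=0)
        keep = nms(boxes, scores, self.cfg.rpn_nms_iou)[: self.cfg.rpn_post_nms]
        return boxes[keep], scores[keep]

    def _assign_levels(self, boxes: np.ndarray) -> np.ndarray:
        """ROIs up to twice the finest anchor scale read the stride-4 level;
        each further octave moves one level coarser."""
        sizes = np.sqrt(np.prod(np.clip(boxes[:, 2:] - boxes[:, :2], 1, None), axis=1))
        octave = np.ceil(np.log2(sizes / self.cfg.anchor_scales[0])) - 1
        return np.clip(octave, 0, self.cfg.n_levels - 1).astype(int)

    def _roi_features(self, feats, boxes: np.ndarray, out_size: int) -> Tensor:
        """ROI-Align across pyramid levels, restoring the input ordering."""
        levels = self._assign_levels(boxes)
        pieces, order = [], []
        for lvl in range(self.cfg.n_levels):
            idx = np.flatnonzero(levels == lvl)
            if idx.size == 0:
                continue
            pieces.append(roi_align(feats[lvl], boxes[idx], out_size, self.strides[lvl]))
            order.append(idx)
        order = np.concatenate(order)
        aligned = concat(pieces, axis=0) if len(pieces) > 1 else pieces[0]
        return aligned[np.argsort(order)]

    # -- training ----------------------------------------------------------
    def loss(self, image: np.ndarray, target: dict, rng: np.random.Generator | None = None):
        """Combined loss on one image.

        ``target`` holds 'boxes' (G,4 float) and 'masks' (G,H,W bool).
        Returns (total: Tensor, components: dict of floats).
        """
        rng = rng or np.random.default_rng(0)
        gt_boxes = np.asarray(target["boxes"], dtype=float)
        gt_masks = np.asarray(target["masks"])
        if len(gt_boxes) == 0:
            raise ValueError("training targets must contain at least one box")
        feats = self.pyramid(image)
        obj, dlt = self.rpn(feats)

        # ---- RPN losses
        anchors, obj_flat, dlt_flat = [], [], []
        for level, (o, d) in enumerate(zip(obj, dlt)):
            h, w = o.shape[2], o.shape[3]
            a = len(self.cfg.anchor_ratios)
            obj_flat.append(o.transpose(0, 2, 3, 1).reshape(-1, 1))
            dlt_flat.append(d.transpose(0, 2, 3, 1).reshape(-1, 4))
            anchors.append(self.anchors_for(level, (h, w)).reshape(a, h * w, 4)
                           .transpose(1, 0, 2).reshape(-1, 4))
        anchors = np.concatenate(anchors, axis=0)
        obj_all = concat(obj_flat, axis=0)
        dlt_all = concat(dlt_flat, axis=0)

        iou = box_iou_matrix(anchors, gt_boxes)
        if len(gt_boxes):
            best_gt = iou.argmax(axis=1)
            best_iou = iou.max(axis=1)
        else:
            best_gt = np.zeros(len(anchors), dtype=int)
            best_iou = np.zeros(len(anchors))
        labels = np.full(len(anchors), -1, dtype=int)  # -1 = ignore
        labels[best_iou < 0.3] = 0
        labels[best_iou >= 0.7] = 1
        if len(gt_boxes):
            labels[iou.argmax(axis=0)] = 1  # force a positive per GT
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        if len(pos) > 64:
            pos = rng.choice(pos, 64, replace=False)
        n_neg = min(len(neg), max(len(pos), 1) * 3)
        neg = rng.choice(neg, n_neg, replace=False)
        sample = np.concatenate([pos, neg])
        rpn_obj = bce_with_logits(obj_all[sample], labels[sample].reshape(-1, 1))
        if len(pos):
            tgt = encode_deltas(anchors[pos], gt_boxes[best_gt[pos]])
            rpn_box = smooth_l1(dlt_all[pos], tgt)
        else:
            rpn_box = Tensor(0.0)

        # ---- ROI sampling: proposals + GT boxes
        proposals, _ = self._proposals(obj, dlt, training=True)
        rois = np.concatenate([proposals, gt_boxes], axis=0) if len(gt_boxes) else proposals
        iou_r = box_iou_matrix(rois, gt_boxes)
        roi_best = iou_r.argmax(axis=1)
        roi_iou = iou_r.max(axis=1) if len(gt_boxes) else np.zeros(len(rois))
        fg = np.flatnonzero(roi_iou >= 0.5)
        bg = np.flatnonzero(roi_iou < 0.5)
        if len(fg) > 32:
            fg = rng.choice(fg, 32, replace=False)
        n_bg = min(len(bg), max(len(fg), 8))
        if n_bg:
            bg = rng.choice(bg, n_bg, replace=False)
        else:
            bg = np.empty(0, dtype=int)
        sample = np.concatenate([fg, bg])
        roi_boxes = rois[sample]
        roi_labels = (roi_iou[sample] >= 0.5).astype(np.float32)

        aligned = self._roi_features(feats, roi_boxes, self.cfg.roi_size)
        cls_logit, reg = self.box_head(aligned)
        roi_cls = bce_with_logits(cls_logit, roi_labels.reshape(-1, 1))
        if len(fg):
            fg_local = np.arange(len(fg))
            tgt = encode_deltas(roi_boxes[fg_local], gt_boxes[roi_best[sample][fg_local]])
            roi_box = smooth_l1(reg[fg_local], tgt)
            # ---- mask loss on foreground ROIs
            mask_feats = self._roi_features(feats, roi_boxes[fg_local], self.cfg.mask_roi_size)
            mask_logits = self.mask_head(mask_feats)
            msz = mask_logits.shape[2]
            targets = np.stack([
                _crop_mask(gt_masks[roi_best[sample][i]], roi_boxes[i], msz) for i in fg_local
            ])
            roi_mask = bce_with_logits(mask_logits, targets.reshape(-1, 1, msz, msz))
        else:
            roi_box = Tensor(0.0)
            roi_mask = Tensor(0.0)

        components = {
            "rpn_objectness": float(rpn_obj.data),
            "rpn_box": float(rpn_box.data),
            "classification": float(roi_cls.data),
            "box_regression": float(roi_box.data),
            "mask": float(roi_mask.data),
        }
        total = rpn_obj + rpn_box + roi_cls + roi_box + roi_mask
        if not np.isfinite(total.data):
            bad = [k for k, v in components.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss component(s): {bad}")
        return total, components

    # -- inference ----------------------------------------------------------
    def predict(self, image) -> list:
        """Run detection on a 2-D image (a FusedImage or array in [0, 1]).

        The image is zero-padded to the network input size; detections are
        returned in the original coordinates.  Images larger than
        ``input_size`` must go through the tiling module instead.
        """
        pixels = getattr(image, "pixels", image)
        pixels = np.asarray(pixels, dtype=np.float32)
        h0, w0 = pixels.shape
        size = self.cfg.input_size
        if h0 > size or w0 > size:
            raise ValueError(
                f"image of shape {pixels.shape} exceeds the network input size {size}; "
                "use neuroseg2.tiling to split it into tiles and merge the detections")
        padded = np.zeros((size, size), dtype=np.float32)
        padded[:h0, :w0] = pixels

        feats = self.pyramid(padded)
        obj, dlt = self.rpn(feats)
        proposals, _ = self._proposals(obj, dlt, training=False)
        if len(proposals) == 0:
            return []
        aligned = self._roi_features(feats, proposals, self.cfg.roi_size)
        cls_logit, reg = self.box_head(aligned)
        scores = _stable_sigmoid(cls_logit.data.reshape(-1))
        boxes = np.clip(decode_deltas(proposals, reg.data), 0, size)
        keep = np.flatnonzero(scores >= self.cfg.score_threshold)
        if keep.size == 0:
            return []
        keep = keep[nms(boxes[keep], scores[keep], self.cfg.detection_nms_iou)]
        keep = keep[: self.cfg.max_instances]
        boxes, scores = boxes[keep], scores[keep]

        mask_feats = self._roi_features(feats, boxes, self.cfg.mask_roi_size)
        probs = self.mask_head(mask_feats).sigmoid().data[:, 0]
        detections = []
        for box, score, prob in zip(boxes, scores, probs):
            full = _paste_mask(prob, box, (size, size), self.cfg.mask_threshold)
            full = full[:h0, :w0]
            if not full.any():
                continue
            r0, c0, r1, c1 = box
            detections.append(Detection(full, (float(r0), float(c0), float(r1), float(c1)),
                                        float(score)))
        return _dedup_masks(detections, self.cfg.detection_nms_iou)


def _dedup_masks(detections: list, iou_threshold: float) -> list:
    """Mask-level non-maximum suppression: box NMS can keep two hits on one
    soma whose boxes barely overlap; drop the lower-scoring one when the
    pasted masks overlap strongly."""
    kept = []
    for det in sorted(detections, key=lambda d: -d.score):
        duplicate = False
        for other in kept:
            inter = np.logical_and(det.mask, other.mask).sum()
            union = np.logical_or(det.mask, other.mask).sum()
            if union and inter / union >= iou_threshold:
                duplicate = True
                break
        if not duplicate:
            kept.append(det)
    return kept


def _crop_mask(mask: np.ndarray, box: np.ndarray, out: int) -> np.ndarray:
    """Sample a GT mask at the ROI grid's bin centres: cell (i, j) of the
    out x out target reads the mask pixel under image point
    box_origin + (i + 0.5) / out * box_extent, matching roi_align exactly."""
    h, w = mask.shape
    r0, c0, r1, c1 = box
    ys = r0 + (np.arange(out) + 0.5) / out * (r1 - r0)
    xs = c0 + (np.arange(out) + 0.5) / out * (c1 - c0)
    yi = np.clip(np.floor(ys).astype(int), 0, h - 1)
    xi = np.clip(np.floor(xs).astype(int), 0, w - 1)
    inside = ((ys >= 0) & (ys < h))[:, None] & ((xs >= 0) & (xs < w))[None, :]
    return (mask[yi][:, xi].astype(np.float32)) * inside


def _paste_mask(prob: np.ndarray, box: np.ndarray, canvas_shape, threshold: float) -> np.ndarray:
    """Resample an ROI-grid probability patch back onto the canvas with the
    inverse of the _crop_mask geometry (bilinear)."""
    h, w = canvas_shape
    p = prob.shape[0]
    r0, c0, r1, c1 = box
    out = np.zeros((h, w), dtype=bool)
    bh, bw = r1 - r0, c1 - c0
    if bh <= 0 or bw <= 0:
        return out
    r0i, c0i = max(int(np.floor(r0)), 0), max(int(np.floor(c0)), 0)
    r1i, c1i = min(int(np.ceil(r1)), h), min(int(np.ceil(c1)), w)
    if r1i <= r0i or c1i <= c0i:
        return out
    gy = ((np.arange(r0i, r1i) + 0.5) - r0) / bh * p - 0.5
    gx = ((np.arange(c0i, c1i) + 0.5) - c0) / bw * p - 0.5
    gy = np.clip(gy, 0, p - 1)
    gx = np.clip(gx, 0, p - 1)
    y0 = np.floor(gy).astype(int)
    x0 = np.floor(gx).astype(int)
    y1 = np.minimum(y0 + 1, p - 1)
    x1 = np.minimum(x0 + 1, p - 1)
    wy = (gy - y0)[:, None]
    wx = (gx - x0)[None, :]
    patch = (prob[np.ix_(y0, x0)] * (1 - wy) * (1 - wx) + prob[np.ix_(y0, x1)] * (1 - wy) * wx
             + prob[np.ix_(y1, x0)] * wy * (1 - wx) + prob[np.ix_(y1, x1)] * wy * wx)
    out[r0i:r1i, c0i:c1i] = patch >= threshold
    return out


def build_model(cfg: ModelConfig, seed: int = 0) -> NeuroSegModel:
    """Construct the network from its configuration (deterministic per seed)."""
    return NeuroSegModel(cfg, seed=seed)
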