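"""Scoring of detected neuron masks against ground truth.

A detection is a true positive when it can be assigned one-to-one to a ground
truth (GT) mask under the distance

    Dist(gt, det) = 1 - IoU(gt, det)   if IoU >= 0.5, or one mask contains
                                       the other,
                  = infinity           otherwise,

with the assignment chosen by the Hungarian algorithm to minimise total cost;
infinite-cost pairs are excluded from the assignment.  Precision, recall and
F1 then follow from the matched-pair count N_TP, the GT count N_GT and the
detection count N_detected:

    recall = N_TP / N_GT,  precision = N_TP / N_detected,
    F1 = 2 * precision * recall / (precision + recall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "NeuronMask",
    "MaskSet",
    "MatchResult",
    "MetricsReport",
    "iou",
    "pair_distance",
    "match",
    "metrics",
    "f1_score",
    "evaluate_masks",
    "IOU_THRESHOLD",
]

IOU_THRESHOLD = 0.5


@dataclass(frozen=True)
class NeuronMask:
    """One neuron's pixel support: a frozenset of 0-based (row, col) pairs."""

    pixels: frozenset

    def __post_init__(self):
        if not self.pixels:
            raise ValueError("a neuron mask must contain at least one pixel")
        object.__setattr__(self, "pixels", frozenset((int(r), int(c)) for r, c in self.pixels))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "NeuronMask":
        rows, cols = np.nonzero(np.asarray(arr))
        return cls(frozenset(zip(rows.tolist(), cols.tolist())))

    def to_array(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        out[list(rows), list(cols)] = True
        return out

    @property
    def area(self) -> int:
        return len(self.pixels)

    def centroid(self):
        arr = np.array(sorted(self.pixels), dtype=float)
        return tuple(arr.mean(axis=0))


@dataclass
class MaskSet:
    """An ordered collection of neuron masks over one field of view."""

    masks: list
    shape: tuple

    def __post_init__(self):
        h, w = self.shape
        for i, m in enumerate(self.masks):
            for r, c in m.pixels:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(f"mask {i} has out-of-bounds pixel ({r}, {c}) for shape {self.shape}")

    def __len__(self):
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i):
        return self.masks[i]

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "MaskSet":
        labels = np.asarray(labels)
        masks = [NeuronMask.from_array(labels == k) for k in np.unique(labels) if k != 0]
        return cls(masks, labels.shape)

    def to_label_image(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.uint16)
        for i, m in enumerate(self.masks):
            rows, cols = zip(*m.pixels)
            out[list(rows), list(cols)] = i + 1
        return out


@dataclass
class MatchResult:
    pairs: list = field(default_factory=list)  # (gt_id, det_id, cost)
    unmatched_gt: list = field(default_factory=list)
    unmatched_det: list = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return len(self.pairs)


@dataclass
class MetricsReport:
    n_tp: int
    n_gt: int
    n_detected: int
    precision: float
    recall: float
    f1: float

    def rounded(self, ndigits: int = 4) -> "MetricsReport":
        return MetricsReport(
            self.n_tp, self.n_gt, self.n_detected,
            round(self.precision, ndigits), round(self.recall, ndigits), round(self.f1, ndigits),
        )

    def __str__(self):
        r = self.rounded()
        return (f"precision = {r.precision}, recall = {r.recall}, F1-score = {r.f1} "
                f"(N_TP = {self.n_tp}, N_GT = {self.n_gt}, N_detected = {self.n_detected})")


def iou(m1: NeuronMask, m2: NeuronMask) -> float:
    """Intersection-over-union of two binary masks."""
    inter = len(m1.pixels & m2.pixels)
    union = len(m1.pixels | m2.pixels)
    return inter / union


def pair_distance(gt: NeuronMask, det: NeuronMask) -> float:
    """Assignment cost between a GT and a detected mask.

    Finite (1 - IoU) when the overlap is strong (IoU >= 0.5) or when one mask
    contains the other; infinite otherwise, meaning the pair may never match.
    """
    j = iou(gt, det)
    contained = gt.pixels <= det.pixels or det.pixels <= gt.pixels
    if j >= IOU_THRESHOLD or contained:
        return 1.0 - j
    return math.inf


def match(gt: MaskSet, det: MaskSet) -> MatchResult:
    """Minimum-cost one-to-one assignment of detections to GT masks.

    Infinite entries are replaced by a finite sentinel larger than any total
    finite assignment before running the Hungarian solver, then sentinel
    pairs are dropped, so the sentinel can never displace a finite match.
    """
    n_gt, n_det = len(gt), len(det)
    if n_gt == 0 or n_det == 0:
        return MatchResult([], list(range(n_gt)), list(range(n_det)))
    cost = np.array([[pair_distance(g, d) for d in det] for g in gt], dtype=float)
    finite = np.isfinite(cost)
    sentinel = min(n_gt, n_det) * 1.0 + 1.0  # finite costs are < 1 each
    solver_cost = np.where(finite, cost, sentinel)
    rows, cols = linear_sum_assignment(solver_cost)
    pairs = [(int(r), int(c), float(cost[r, c])) for r, c in zip(rows, cols) if finite[r, c]]
    matched_gt = {r for r, _, _ in pairs}
    matched_det = {c for _, c, _ in pairs}
    return MatchResult(
        pairs,
        [i for i in range(n_gt) if i not in matched_gt],
        [j for j in range(n_det) if j not in matched_det],
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(n_tp: int, n_gt: int, n_detected: int) -> MetricsReport:
    """Precision/recall/F1 from the matched, GT and detected counts."""
    if min(n_tp, n_gt, n_detected) < 0 or n_tp > min(n_gt, n_detected):
        raise ValueError(f"inconsistent counts: n_tp={n_tp}, n_gt={n_gt}, n_detected={n_detected}")
    precision = n_tp / n_detected if n_detected else 0.0
    recall = n_tp / n_gt if n_gt else 0.0
    return MetricsReport(n_tp, n_gt, n_detected, precision, recall, f1_score(precision, recall))


def evaluate_masks(gt: MaskSet, det: MaskSet) -> MetricsReport:
    """Match then score: the standard end-to-end evaluation call."""
    return metrics(match(gt, det).n_tp, len(gt), len(det))
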