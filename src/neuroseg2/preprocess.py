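"""Video-to-image preprocessing: average projection, correlation map, fusion.

A motion-corrected movie is collapsed to a single 2-D network input in three
steps.  The average projection captures anatomy (baseline fluorescence); the
weighted correlation map captures activity, scoring each pixel by how
coherently its temporal trace co-fluctuates with its neighbours:

    c_w(f_1, f_2, ...) = || sum_i a_i f_i ||_2 / sum_i a_i ||f_i||_2

where f_i are the (temporally centred, by default) traces in a Gaussian
neighbourhood and a_i > 0 the Gaussian weights.  By Cauchy-Schwarz and the
triangle inequality c_w is always in [0, 1]; identical traces give 1, and
incoherent traces give small values, so active somata stand out even when
they are invisible in the average image.  The two images are min-max
normalised and convexly combined into the fused input.

The segment-splitting protocol converts one video into n+1 fused images: one
per contiguous equal temporal segment plus one for the whole movie.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VideoStack",
    "CorrelationConfig",
    "FusionConfig",
    "FusedImage",
    "average_projection",
    "weighted_correlation",
    "correlation_map",
    "fuse",
    "split_and_project",
    "minmax_normalize",
]


@dataclass
class VideoStack:
    """A T x H x W motion-corrected fluorescence movie."""

    frames: np.ndarray
    frame_rate_hz: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError(f"video must be a non-empty T x H x W stack, got shape {self.frames.shape}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("video contains non-finite values")
        if self.frame_rate_hz is not None and self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class CorrelationConfig:
    """Neighbourhood definition for the correlation map.

    The default 7x7 support (radius 3, sigma 1.5) is local relative to somata
    of 10-30 px diameter.  ``center_traces`` subtracts each pixel's temporal
    mean first; without it a shared baseline drives c_w toward 1 everywhere.
    """

    neighborhood_radius: int = 3
    gaussian_sigma: float = 1.5
    center_traces: bool = True

    def __post_init__(self):
        if self.neighborhood_radius < 1:
            raise ValueError("neighborhood_radius must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")

    def kernel(self) -> np.ndarray:
        """Strictly positive Gaussian weights on the (2r+1)^2 window."""
        r = self.neighborhood_radius
        g = np.arange(-r, r + 1, dtype=float)
        k = np.exp(-(g[:, None] ** 2 + g[None, :] ** 2) / (2.0 * self.gaussian_sigma**2))
        return k


@dataclass
class FusionConfig:
    """Convex-combination weight of the average image vs the correlation map."""

    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class FusedImage:
    """H x W image in [0, 1] combining average projection and correlation map."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("fused image must be 2-D")
        if self.pixels.size and (self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9):
            raise ValueError("fused image values must lie in [0, 1]")

    @property
    def shape(self):
        return self.pixels.shape


def average_projection(video: VideoStack) -> np.ndarray:
    """Per-pixel temporal mean of the movie."""
    return video.frames.mean(axis=0)


def weighted_correlation(traces: np.ndarray, weights: np.ndarray) -> float:
    """c_w for one neighbourhood: traces (n, T), strictly positive weights (n,)."""
    traces = np.asarray(traces, dtype=float)
    weights = np.asarray(weights, dtype=float)
    denom = float(weights @ np.linalg.norm(traces, axis=1))
    if denom == 0.0:
        return 0.0
    num = float(np.linalg.norm(weights @ traces))
    return num / denom


def correlation_map(video: VideoStack, cfg: CorrelationConfig | None = None) -> np.ndarray:
    """Weighted multidimensional correlation c_w at every pixel.

    The neighbourhood is truncated at image borders (out-of-range taps are
    dropped, which is equivalent to renormalising because c_w is invariant to
    a common scaling of the weights).  Pixels whose every neighbourhood trace
    has zero norm get c_w = 0.
    """
    if cfg is None:
        cfg = CorrelationConfig()
    if video.n_frames < 2:
        warnings.warn("correlation map of a video with < 2 frames is identically 0", stacklevel=2)
        return np.zeros(video.shape)
    f = video.frames
    if cfg.center_traces:
        f = f - f.mean(axis=0, keepdims=True)
    t, h, w = f.shape
    r = cfg.neighborhood_radius
    kernel = cfg.kernel()
    norms = np.sqrt((f**2).sum(axis=0))  # ||f_i|| per pixel
    num_vec = np.zeros((t, h, w))  # sum_i a_i f_i, accumulated per offset
    denom = np.zeros((h, w))  # sum_i a_i ||f_i||
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            a = kernel[di + r, dj + r]
            src_r = slice(max(di, 0), h + min(di, 0))
            dst_r = slice(max(-di, 0), h + min(-di, 0))
            src_c = slice(max(dj, 0), w + min(dj, 0))
            dst_c = slice(max(-dj, 0), w + min(-dj, 0))
            num_vec[:, dst_r, dst_c] += a * f[:, src_r, src_c]
            denom[dst_r, dst_c] += a * norms[src_r, src_c]
    num = np.sqrt((num_vec**2).sum(axis=0))
    out = np.zeros((h, w))
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return np.clip(out, 0.0, 1.0)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Scale an image to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        logger.warning("constant image normalises to all zeros (min == max == %g)", lo)
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def fuse(avg: np.ndarray, corr: np.ndarray, cfg: FusionConfig | None = None,
         provenance: dict | None = None) -> FusedImage:
    """Min-max normalise both inputs then combine: alpha*avg + (1-alpha)*corr."""
    if cfg is None:
        cfg = FusionConfig()
    avg = np.asarray(avg, dtype=np.float64)
    corr = np.asarray(corr, dtype=np.float64)
    if avg.shape != corr.shape:
        raise ValueError(f"image shapes differ: {avg.shape} vs {corr.shape}")
    pixels = cfg.alpha * minmax_normalize(avg) + (1.0 - cfg.alpha) * minmax_normalize(corr)
    return FusedImage(np.clip(pixels, 0.0, 1.0), provenance or {})


def segment_bounds(n_frames: int, n_segments: int) -> list:
    """Partition [0, n_frames) into contiguous near-equal segments; the
    T mod n leftover frames go to the earliest segments."""
    base, extra = divmod(n_frames, n_segments)
    bounds, start = [], 0
    for i in range(n_segments):
        length = base + (1 if i < extra else 0)
        bounds.append((start, start + length))
        start += length
    return bounds


def _project(video: VideoStack, corr_cfg, fusion_cfg, provenance) -> FusedImage:
    avg = average_projection(video)
    corr = correlation_map(video, corr_cfg)
    return fuse(avg, corr, fusion_cfg, provenance)


def split_and_project(video: VideoStack, n_segments: int = 6,
                      corr_cfg: CorrelationConfig | None = None,
                      fusion_cfg: FusionConfig | None = None,
                      name: str = "video") -> list:
    """The n-segment protocol: n fused images from an evenly divided video
    plus one from the whole video (n + 1 in total; 7 with the default 6)."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if video.n_frames < n_segments:
        raise ValueError(f"video has {video.n_frames} frames, fewer than {n_segments} segments")
    images = []
    for i, (lo, hi) in enumerate(segment_bounds(video.n_frames, n_segments)):
        seg = VideoStack(video.frames[lo:hi], video.frame_rate_hz)
        images.append(_project(seg, corr_cfg, fusion_cfg,
                               {"source": name, "segment": i, "frames": (lo, hi)}))
    images.append(_project(video, corr_cfg, fusion_cfg,
                           {"source": name, "segment": "whole", "frames": (0, video.n_frames)}))
    return images
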