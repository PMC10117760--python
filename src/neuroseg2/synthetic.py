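"""Ground-truthed synthetic two-photon Ca2+ movies.

The generator emulates the image structure the segmentation method exploits:

* donut-shaped somata — cytoplasmic indicator expression makes the ring of a
  soma brighter than its centre;
* a mixture of active and inactive neurons — inactive cells keep a static
  baseline above background (anatomy-visible, activity-invisible);
* at least one *sparse* active neuron whose baseline sits at the background,
  so it is invisible in the average projection but lights up the correlation
  map through its rare coherent transients;
* deliberately overlapping neuron pairs;
* additive i.i.d. Gaussian noise.

Transients follow the standard model: Poisson event times convolved with an
exponential-decay kernel.  The rendered movie is

    video[t] = background + sum_k footprint_k * (baseline_k + trace_k[t]) + noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .evaluation import MaskSet, NeuronMask
from .preprocess import VideoStack

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "generate_transients"]

DEFAULT_FRAME_RATE_HZ = 10.0


@dataclass
class SyntheticConfig:
    image_size: tuple = (128, 128)
    n_frames: int = 200
    n_neurons: int = 12
    radius_range: tuple = (5.0, 8.0)
    ring_fraction: float = 0.5          # inner-hole radius / outer radius
    active_fraction: float = 0.6
    transient_rate_hz: float = 0.2      # events per second per active neuron
    decay_tau_frames: float = 5.0
    noise_sigma: float = 2.0            # additive Gaussian s.d., intensity units
    overlap_pairs: int = 1
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    background: float = 20.0            # constant baseline fluorescence
    baseline_amplitude: float = 15.0    # static soma brightness above background
    transient_amplitude: float = 30.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not (0 < self.ring_fraction < 1):
            raise ValueError("ring_fraction must lie in (0, 1)")
        if not (0 <= self.active_fraction <= 1):
            raise ValueError("active_fraction must lie in [0, 1]")
        if self.radius_range[0] <= 0 or 2 * self.radius_range[1] >= min(h, w):
            raise ValueError("radius_range must be positive and fit in the image")
        if self.overlap_pairs > self.n_neurons // 2:
            raise ValueError("overlap_pairs must be <= n_neurons / 2")
        if self.noise_sigma < 0 or self.transient_rate_hz < 0:
            raise ValueError("noise_sigma and transient_rate_hz must be >= 0")
        if self.decay_tau_frames <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("decay_tau_frames and frame_rate_hz must be > 0")


@dataclass
class GroundTruth:
    masks: MaskSet
    activity_labels: np.ndarray      # bool per neuron
    traces: np.ndarray               # (n_neurons, T) transient time courses
    footprints: np.ndarray           # (n_neurons, H, W) rendered donut profiles
    baselines: np.ndarray            # static brightness above background
    background: float
    sparse_ids: list = field(default_factory=list)

    def noiseless_video(self, n_frames: int | None = None) -> np.ndarray:
        t = self.traces.shape[1] if n_frames is None else n_frames
        amp = self.baselines[:, None] + self.traces[:, :t]      # (n, T)
        movie = np.einsum("nt,nhw->thw", amp, self.footprints)
        return movie + self.background


def generate_transients(n_frames: int, rate_hz: float, tau_frames: float,
                        seed, frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> np.ndarray:
    """Poisson events at ``rate_hz`` convolved with exp(-dt/tau) decay.

    Returns a nonnegative trace of unit event amplitude; expected event count
    is rate * n_frames / frame_rate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_event = rate_hz / frame_rate_hz
    events = rng.random(n_frames) < p_event
    kernel = np.exp(-np.arange(n_frames) / tau_frames)
    trace = np.convolve(events.astype(float), kernel)[:n_frames]
    return trace


def _donut_profile(shape, center, radius, ring_fraction, blur_sigma=1.0,
                   hole_level=0.3) -> np.ndarray:
    """Annulus of unit ring brightness with a dimmer centre, Gaussian-smoothed."""
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    prof = np.zeros(shape)
    prof[d <= radius] = hole_level
    prof[(d <= radius) & (d >= ring_fraction * radius)] = 1.0
    return gaussian_filter(prof, blur_sigma)


def _place_centers(cfg: SyntheticConfig, rng: np.random.Generator):
    """Rejection-sample soma centres with a minimum separation, then place the
    designated overlap partners close to their mates."""
    h, w = cfg.image_size
    r_max = cfg.radius_range[1]
    margin = r_max + 2
    n_primary = cfg.n_neurons - cfg.overlap_pairs
    # primaries far enough apart that even two overlap partners straying
    # toward each other cannot make their disks touch
    pad = 2.2 * cfg.radius_range[0] if cfg.overlap_pairs else 0.0
    min_sep = 2 * r_max + pad + 2
    centers = []
    for _ in range(n_primary):
        for _attempt in range(2000):
            cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_sep**2 for c in centers):
                centers.append(cand)
                break
        else:
            raise ValueError(f"could not place {cfg.n_neurons} neurons of radius <= {r_max} "
                             f"in a {h}x{w} field; reduce n_neurons or radius_range")
    partners = []
    for k in range(cfg.overlap_pairs):
        mate = centers[k]
        ang = rng.uniform(0, 2 * np.pi)
        dist = 1.1 * cfg.radius_range[0]   # close enough that the disks share pixels
        cand = (float(np.clip(mate[0] + dist * np.sin(ang), margin, h - margin)),
                float(np.clip(mate[1] + dist * np.cos(ang), margin, w - margin)))
        partners.append(cand)
    return centers + partners


def generate(cfg: SyntheticConfig) -> tuple:
    """Render a (VideoStack, GroundTruth) pair, reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    n = cfg.n_neurons
    centers = _place_centers(cfg, rng)
    radii = rng.uniform(*cfg.radius_range, size=n)

    footprints = np.stack([
        _donut_profile((h, w), centers[k], radii[k], cfg.ring_fraction) for k in range(n)
    ])
    masks = []
    rr, cc = np.ogrid[:h, :w]
    for k in range(n):
        d2 = (rr - centers[k][0]) ** 2 + (cc - centers[k][1]) ** 2
        masks.append(NeuronMask.from_array(d2 <= radii[k] ** 2))
    mask_set = MaskSet(masks, (h, w))

    n_active = max(int(round(cfg.active_fraction * n)), 1)
    active = np.zeros(n, dtype=bool)
    active[rng.choice(n, size=n_active, replace=False)] = True

    baselines = cfg.baseline_amplitude * rng.uniform(0.7, 1.3, size=n)
    # one active neuron is made average-invisible: background-level baseline,
    # sparse but guaranteed activity (the correlation map's raison d'etre).
    # Chosen outside the overlap pairs so no partner's baseline lights its mask.
    lone = [k for k in range(cfg.overlap_pairs, n - cfg.overlap_pairs)] or list(range(n))
    sparse_id = int(lone[0])
    active[sparse_id] = True
    baselines[sparse_id] = 0.0

    traces = np.zeros((n, cfg.n_frames))
    for k in range(n):
        if not active[k]:
            continue
        traces[k] = cfg.transient_amplitude * generate_transients(
            cfg.n_frames, cfg.transient_rate_hz, cfg.decay_tau_frames, rng, cfg.frame_rate_hz)
    # guarantee the sparse neuron actually fires (a handful of events)
    if traces[sparse_id].max() == 0.0:
        kernel = np.exp(-np.arange(cfg.n_frames) / cfg.decay_tau_frames)
        events = np.zeros(cfg.n_frames)
        events[rng.integers(0, cfg.n_frames, size=3)] = 1.0
        traces[sparse_id] = cfg.transient_amplitude * np.convolve(events, kernel)[: cfg.n_frames]

    gt = GroundTruth(mask_set, active, traces, footprints, baselines,
                     cfg.background, [sparse_id])
    movie = gt.noiseless_video(cfg.n_frames)
    if cfg.noise_sigma > 0:
        movie = movie + rng.normal(0.0, cfg.noise_sigma, size=movie.shape)
    return VideoStack(movie, cfg.frame_rate_hz), gt
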