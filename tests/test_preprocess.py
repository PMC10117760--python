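"""Average projection, correlation map, fusion and segment splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuroseg2 as ns
from neuroseg2.preprocess import minmax_normalize, segment_bounds


def brute_force_average(frames):
    t, h, w = frames.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for k in range(t):
                acc += frames[k, r, c]
            out[r, c] = acc / t
    return out


def brute_force_correlation(frames, cfg):
    """Direct per-pixel implementation of the weighted correlation."""
    f = frames - frames.mean(axis=0) if cfg.center_traces else frames
    t, h, w = f.shape
    r = cfg.neighborhood_radius
    kern = cfg.kernel()
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            traces, weights = [], []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        traces.append(f[:, ii, jj])
                        weights.append(kern[di + r, dj + r])
            out[i, j] = ns.weighted_correlation(np.array(traces), np.array(weights))
    return out


class TestAverageProjection:
    def test_constant_video(self):
        video = ns.VideoStack(np.full((4, 5, 6), 5.0))
        assert np.array_equal(ns.average_projection(video), np.full((5, 6), 5.0))

    def test_two_frames_mean(self):
        a = np.arange(12.0).reshape(3, 4)
        b = a[::-1, ::-1].copy()
        video = ns.VideoStack(np.stack([a, b]))
        assert np.allclose(ns.average_projection(video), (a + b) / 2)

    def test_matches_brute_force_on_synthetic_video(self):
        video, _ = ns.generate(ns.SyntheticConfig(
            image_size=(24, 24), n_frames=100, n_neurons=1, overlap_pairs=0, seed=0))
        assert np.allclose(ns.average_projection(video), brute_force_average(video.frames))

    def test_empty_video_rejected(self):
        with pytest.raises(ValueError):
            ns.VideoStack(np.zeros((0, 4, 4)))


class TestWeightedCorrelation:
    def test_identical_traces_give_one(self):
        trace = np.array([1.0, -2.0, 3.0, 0.5])
        traces = np.tile(trace, (9, 1))
        weights = np.random.default_rng(0).uniform(0.1, 1.0, size=9)
        assert ns.weighted_correlation(traces, weights) == pytest.approx(1.0)

    def test_orthogonal_pair_gives_sqrt2_over_2(self):
        f1 = np.array([1.0, 0.0])
        f2 = np.array([0.0, 1.0])
        c = ns.weighted_correlation(np.stack([f1, f2]), np.array([0.5, 0.5]))
        assert c == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_zero_norm_traces_give_zero(self):
        assert ns.weighted_correlation(np.zeros((4, 7)), np.ones(4)) == 0.0


class TestCorrelationMap:
    def test_identical_trace_field_gives_one_everywhere(self):
        trace = np.array([0.0, 3.0, 1.0, 4.0, 2.0])
        frames = np.tile(trace[:, None, None], (1, 8, 9))
        video = ns.VideoStack(frames)
        corr = ns.correlation_map(video)
        assert np.allclose(corr, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        video = ns.VideoStack(rng.normal(10, 2, size=(20, 10, 11)))
        cfg = ns.CorrelationConfig(neighborhood_radius=2, gaussian_sigma=1.0)
        assert np.allclose(ns.correlation_map(video, cfg),
                           brute_force_correlation(video.frames, cfg), atol=1e-10)

    def test_active_neuron_brighter_than_background(self):
        video, gt = ns.generate(ns.SyntheticConfig(
            image_size=(48, 48), n_frames=150, n_neurons=2, overlap_pairs=0,
            active_fraction=1.0, seed=0))
        corr = ns.correlation_map(video)
        inside = np.any([m.to_array((48, 48)) for m in gt.masks], axis=0)
        assert corr[inside].mean() > corr[~inside].mean()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_values_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        video = ns.VideoStack(rng.normal(size=(6, 7, 7)))
        corr = ns.correlation_map(video, ns.CorrelationConfig(neighborhood_radius=1))
        assert corr.min() >= 0.0 and corr.max() <= 1.0

    def test_invariant_to_frame_permutation(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(5, 1, size=(30, 9, 9))
        perm = rng.permutation(30)
        a = ns.correlation_map(ns.VideoStack(frames))
        b = ns.correlation_map(ns.VideoStack(frames[perm]))
        assert np.allclose(a, b)
        assert np.allclose(ns.average_projection(ns.VideoStack(frames)),
                           ns.average_projection(ns.VideoStack(frames[perm])))


class TestFuse:
    def test_alpha_one_returns_normalized_average(self):
        rng = np.random.default_rng(0)
        avg, corr = rng.uniform(0, 50, (12, 12)), rng.uniform(0, 1, (12, 12))
        fused = ns.fuse(avg, corr, ns.FusionConfig(alpha=1.0))
        assert np.allclose(fused.pixels, minmax_normalize(avg))

    def test_identical_inputs_any_alpha(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 9, (6, 6))
        fused = ns.fuse(img, img, ns.FusionConfig(alpha=0.3))
        assert np.allclose(fused.pixels, minmax_normalize(img))

    def test_direct_evaluation(self):
        avg = np.array([[10.0, 15.0], [20.0, 10.0]])
        corr = np.array([[0.0, 0.25], [1.0, 0.0]])
        fused = ns.fuse(avg, corr, ns.FusionConfig(alpha=0.5))
        assert fused.pixels[0, 1] == pytest.approx(0.5 * 0.5 + 0.5 * 0.25)

    def test_constant_image_normalizes_to_zero(self):
        fused = ns.fuse(np.full((4, 4), 7.0), np.eye(4), ns.FusionConfig(alpha=1.0))
        assert np.allclose(fused.pixels, 0.0)

    def test_monotone_in_each_input(self):
        rng = np.random.default_rng(2)
        avg, corr = rng.uniform(0, 10, (5, 5)), rng.uniform(0, 10, (5, 5))
        base = ns.fuse(avg, corr).pixels
        bumped = avg.copy()
        # raise an interior pixel without changing the min/max of the image
        idx = np.unravel_index(np.argsort(avg, axis=None)[10], avg.shape)
        bumped[idx] = (avg[idx] + avg.max()) / 2
        assert ns.fuse(bumped, corr).pixels[idx] >= base[idx]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ns.fuse(np.zeros((3, 3)), np.zeros((4, 4)))


class TestSplitAndProject:
    def test_default_six_segments_give_seven_images(self):
        video, _ = ns.generate(ns.SyntheticConfig(
            image_size=(24, 24), n_frames=60, n_neurons=1, overlap_pairs=0, seed=0))
        images = ns.split_and_project(video, 6)
        assert len(images) == 7

    def test_one_frame_segments(self):
        frames = np.random.default_rng(0).uniform(1, 2, size=(6, 5, 5))
        images = ns.split_and_project(ns.VideoStack(frames), 6)
        assert len(images) == 7
        # a single-frame segment has no temporal structure: the fused image
        # is alpha * normalised frame
        for i in range(6):
            expected = 0.5 * minmax_normalize(frames[i])
            assert np.allclose(images[i].pixels, expected)

    def test_remainder_rule_partition(self):
        bounds = segment_bounds(100, 6)
        lengths = [hi - lo for lo, hi in bounds]
        assert lengths == [17, 17, 17, 17, 16, 16]
        covered = [f for lo, hi in bounds for f in range(lo, hi)]
        assert covered == list(range(100))

    def test_whole_video_average_is_length_weighted_segment_mean(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 5, size=(50, 6, 6))
        video = ns.VideoStack(frames)
        bounds = segment_bounds(50, 6)
        weighted = sum((hi - lo) * frames[lo:hi].mean(axis=0) for lo, hi in bounds) / 50
        assert np.allclose(weighted, ns.average_projection(video))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            ns.split_and_project(ns.VideoStack(np.zeros((3, 4, 4)) + 1.0), 6)
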