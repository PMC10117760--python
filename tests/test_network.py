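"""Architecture components: ECA gating, feature fusion, ablation arms,
the combined loss, and prediction on the overfit toy model."""

import numpy as np
import pytest

import neuroseg2 as ns
from neuroseg2.autograd import Tensor
from neuroseg2.evaluation import MaskSet, NeuronMask, evaluate_masks, iou, match
from neuroseg2.network import num_lateral_connections
from neuroseg2.training import masks_to_targets

from conftest import toy_model_config


def eca_oracle(x, weights):
    """Independent GAP -> sliding-window 1-D conv -> logistic -> scale."""
    n, c, h, w = x.shape
    gap = x.mean(axis=(2, 3))
    k = len(weights)
    half = k // 2
    padded = np.pad(gap, ((0, 0), (half, half)))
    conv = np.zeros((n, c))
    for ch in range(c):
        conv[:, ch] = sum(weights[j] * padded[:, ch + j] for j in range(k))
    gate = 1.0 / (1.0 + np.exp(-conv))
    return x * gate[:, :, None, None]


class TestECA:
    def test_zero_input_gives_zero_output(self):
        out = ns.eca(np.zeros((1, 4, 5, 5), dtype=np.float32), kernel=3)
        assert np.allclose(out.data, 0.0)

    def test_single_channel_zero_weight_closed_form(self):
        x = np.ones((1, 1, 3, 3), dtype=np.float32)
        out = ns.eca(x, kernel=1, weights=[0.0])
        assert np.allclose(out.data, 0.5)  # sigmoid(0) * 1

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 4, 6, 5)).astype(np.float32)
        weights = rng.normal(size=3).astype(np.float32)
        out = ns.eca(x, kernel=3, weights=weights)
        assert np.allclose(out.data, eca_oracle(x, weights), atol=1e-5)

    def test_never_changes_sign_gates_in_unit_interval(self):
        from neuroseg2.layers import ECA
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        module = ECA(3, rng=rng)
        gates = module.channel_weights(x).data
        assert np.all((gates > 0) & (gates < 1))
        out = module(x).data
        assert np.all(np.sign(out) == np.sign(np.where(x.data == 0, 0, x.data)))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ns.eca(np.zeros((1, 2, 2, 2), dtype=np.float32), kernel=2)


class TestFuseFeatures:
    def test_add_with_zeros_is_identity(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        out = ns.fuse_features(x, Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)), "add")
        assert np.allclose(out.data, x.data)

    def test_concat_channel_arithmetic(self):
        a = Tensor(np.zeros((1, 256, 2, 2), dtype=np.float32))
        b = Tensor(np.ones((1, 256, 2, 2), dtype=np.float32))
        out = ns.fuse_features(a, b, "concat")
        assert out.shape[1] == 512

    def test_add_channel_mismatch_names_levels(self):
        a = Tensor(np.zeros((1, 8, 2, 2), dtype=np.float32))
        b = Tensor(np.zeros((1, 16, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="P2.*P3"):
            ns.fuse_features(a, b, "add", names=("P2", "P3"))

    def test_reference_config_fusion_modes(self):
        cfg = ns.ModelConfig()
        assert cfg.fusion_up == "add" and cfg.fusion_down == "concat"


class TestBuildModel:
    def test_path_augmentation_gives_five_backbone_levels(self):
        model = ns.build_model(toy_model_config(path_augmentation=True), seed=0)
        img = np.zeros((1, 1, 128, 128), dtype=np.float32)
        feats = model.backbone(Tensor(img))
        assert len(feats) == 5

    def test_fpn_plus_emits_y2_to_y6(self):
        model = ns.build_model(toy_model_config(fpn_plus=True, path_augmentation=True), seed=0)
        assert model.feature_names() == ["Y2", "Y3", "Y4", "Y5", "Y6"]
        feats = model.pyramid(np.zeros((128, 128), dtype=np.float32))
        assert len(feats) == 5

    def test_all_ablation_arms_build_and_differ(self):
        """The four ablation arms are constructible from config alone and
        have pairwise different parameter counts."""
        arms = {
            "full": toy_model_config(),
            "no_attention": toy_model_config(attention="none"),
            "no_path_augmentation": toy_model_config(
                path_augmentation=False, anchor_scales=(8, 16, 24, 32)),
            "no_fpn_plus": toy_model_config(fpn_plus=False),
        }
        counts = {name: ns.build_model(cfg, seed=0).num_parameters()
                  for name, cfg in arms.items()}
        assert len(set(counts.values())) == len(counts)

    def test_eca_parameter_delta_is_laterals_times_kernel(self):
        for kernel in (3, 5):
            with_eca = toy_model_config(attention="eca", eca_kernel=kernel)
            without = toy_model_config(attention="none")
            delta = (ns.build_model(with_eca, seed=0).num_parameters()
                     - ns.build_model(without, seed=0).num_parameters())
            n_laterals = with_eca.n_levels + (with_eca.n_levels - 1)
            assert delta == n_laterals * kernel
            assert num_lateral_connections(with_eca) == n_laterals

    def test_build_is_deterministic(self):
        a = ns.build_model(toy_model_config(), seed=3).state_dict()
        b = ns.build_model(toy_model_config(), seed=3).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ns.ModelConfig(eca_kernel=2)
        with pytest.raises(ValueError):
            ns.ModelConfig(fusion_up="multiply")
        with pytest.raises(ValueError):
            ns.ModelConfig(anchor_scales=(32, 16, 8, 64, 128))


class TestLoss:
    @pytest.fixture(scope="class")
    def toy_batch(self):
        cfg = ns.SyntheticConfig(image_size=(128, 128), n_frames=80, n_neurons=4,
                                 overlap_pairs=0, noise_sigma=1.0, seed=2)
        video, gt = ns.generate(cfg)
        img = ns.fuse(ns.average_projection(video), ns.correlation_map(video)).pixels
        return img, masks_to_targets(gt.masks)

    def test_total_is_sum_of_components(self, toy_batch):
        model = ns.build_model(toy_model_config(), seed=0)
        img, target = toy_batch
        total, comps = model.loss(img, target, rng=np.random.default_rng(0))
        assert float(total.data) == pytest.approx(sum(comps.values()), rel=1e-5)
        assert all(v >= 0 and np.isfinite(v) for v in comps.values())

    def test_single_gradient_step_decreases_loss(self, toy_batch):
        from neuroseg2.layers import SGD
        model = ns.build_model(toy_model_config(), seed=0)
        img, target = toy_batch
        opt = SGD(model.trainable_parameters(), lr=1e-2)
        total0, _ = model.loss(img, target, rng=np.random.default_rng(0))
        total0.backward()
        opt.step()
        total1, _ = model.loss(img, target, rng=np.random.default_rng(0))
        assert float(total1.data) < float(total0.data)

    def test_missing_targets_rejected(self, toy_batch):
        model = ns.build_model(toy_model_config(), seed=0)
        img, _ = toy_batch
        with pytest.raises(ValueError):
            model.loss(img, {"boxes": np.zeros((0, 4)), "masks": np.zeros((0, 128, 128))})


class TestPredict:
    def test_untrained_model_deterministic(self):
        model = ns.build_model(toy_model_config(), seed=0)
        img = np.random.default_rng(0).uniform(0, 1, size=(128, 128))
        d1, d2 = model.predict(img), model.predict(img)
        assert len(d1) == len(d2)
        for a, b in zip(d1, d2):
            assert a.score == b.score and np.array_equal(a.mask, b.mask)

    def test_oversized_image_directs_to_tiling(self):
        model = ns.build_model(toy_model_config(), seed=0)
        with pytest.raises(ValueError, match="tiling"):
            model.predict(np.zeros((300, 300)))

    def test_blank_image_yields_no_detections(self, overfit_model):
        assert overfit_model["model"].predict(np.zeros((128, 128))) == []

    def test_overfit_model_recovers_all_neurons(self, overfit_model, toy_scene):
        """Every synthetic soma is found with mask IoU >= 0.5 against GT."""
        model = overfit_model["model"]
        gt = toy_scene["gt"].masks
        detections = model.predict(toy_scene["image"])
        assert len(detections) == len(gt)
        for d in detections:
            dm = NeuronMask.from_array(d.mask)
            assert max(iou(dm, g) for g in gt) >= 0.5

    def test_horizontal_flip_equivariance(self, overfit_model, toy_scene):
        """Predicting the mirrored scene gives mirrored masks (sanity bound:
        matched detections agree at mean mask-IoU >= 0.9)."""
        model = overfit_model["model"]
        img = toy_scene["image"]
        d1 = model.predict(img)
        d2 = model.predict(img[:, ::-1].copy())
        m1 = MaskSet([NeuronMask.from_array(d.mask) for d in d1], img.shape)
        m2 = MaskSet([NeuronMask.from_array(d.mask[:, ::-1]) for d in d2], img.shape)
        assert len(m1) == len(m2)
        res = match(m1, m2)
        assert res.n_tp == len(m1)
        ious = [1 - cost for _, _, cost in res.pairs]
        assert np.mean(ious) >= 0.9
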