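"""Backbone wiring, head contracts, two-stage training behavior."""

import numpy as np
import pytest

from spermvision.autodiff import Tensor
from spermvision.network import (BackboneConfig, TrainConfig, build_network,
                                 load_checkpoint, predict, save_checkpoint,
                                 stratified_split, train_two_stage)


def tiny_batch(n=4, size=64, seed=0):
    return np.random.default_rng(seed).random((n, 3, size, size))


class TestWiring:
    def test_tiny_stride_arithmetic(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=0)
        out = net.eval().forward(tiny_batch(2), capture=True)
        assert out["conv5"].shape == (2, 128, 2, 2)
        assert out["cbam"].shape == (2, 128, 2, 2)
        assert out["combined"].shape == (2, 256)

    def test_resnet50_stage_channels_configured(self):
        cfg = BackboneConfig(variant="resnet50", input_size=224)
        assert cfg.stage_blocks == (3, 4, 6, 3)
        assert cfg.stage_channels == (256, 512, 1024, 2048)

    def test_cbam_ablation_reduces_to_plain_backbone(self):
        base = build_network(BackboneConfig(variant="tiny", input_size=64), 3,
                             cbam_cfg={"enabled": False}, seed=0)
        assert not base.cbam_enabled
        assert not any("cbam" in name for name in base.state_arrays())
        x = tiny_batch(2)
        out = base.eval().forward(x, capture=True)
        # without CBAM the captured refined map is the raw stage output
        assert np.array_equal(out["cbam"].data, out["conv5"].data)

    def test_wrong_input_size_rejected_with_sizes_named(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=0)
        with pytest.raises(ValueError, match="64"):
            net.forward(tiny_batch(1, size=32))

    def test_n_classes_validated(self):
        with pytest.raises(ValueError):
            build_network(BackboneConfig(variant="tiny", input_size=64), 1)


class TestHead:
    def test_probability_rows_sum_to_one(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=1)
        probs = net.eval().forward(tiny_batch(5))["probs"].data
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_forward_deterministic_despite_dropout(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=1)
        net.eval()
        x = tiny_batch(3)
        assert np.array_equal(net.forward(x)["probs"].data, net.forward(x)["probs"].data)

    def test_forward_head_descriptor_is_twice_channels(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=1)
        net.eval()
        fmap = np.random.default_rng(0).random((2, 128, 2, 2))
        probs = net.forward_head(fmap)
        assert probs.shape == (2, 3)
        assert net.head_fc.weight.shape == (256, 3)

    def test_uniform_logits_predict_class_zero(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=1)
        net.head_fc.weight.data[:] = 0.0
        net.head_fc.bias.data[:] = 0.0
        from spermvision.network import TrainedNetwork

        trained = TrainedNetwork(net=net, config=net.cfg, train_config=TrainConfig(),
                                 class_names=["a", "b", "c"])
        labels, probs = predict(trained, tiny_batch(4))
        assert np.allclose(probs, 1 / 3)
        assert np.array_equal(labels, np.zeros(4, dtype=int))


@pytest.fixture(scope="module")
def trained_small():
    rng = np.random.default_rng(0)
    x = rng.random((36, 3, 64, 64))
    # make classes trivially separable by brightness so descent is visible
    y = np.repeat([0, 1, 2], 12)
    x[y == 1] += 0.35
    x[y == 2] -= 0.35
    x = np.clip(x, 0, 1)
    net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=5)
    backbone_before = {k: v.copy() for k, v in net.state_arrays().items()}
    cfg = TrainConfig(stage1_epochs=5, stage2_epochs=2, seed=5)
    trained = train_two_stage(net, x, y, ["a", "b", "c"], cfg)
    return trained, x, y, backbone_before


class TestTraining:
    def test_loss_decreases(self, trained_small):
        trained, *_ = trained_small
        hist = trained.history["stage1"] + trained.history["stage2"]
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_stage1_backbone_parameters_bit_identical(self):
        rng = np.random.default_rng(1)
        x = rng.random((12, 3, 64, 64))
        y = np.repeat([0, 1, 2], 4)
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=2)
        before = {id(p): p.data.copy() for p in net.backbone_parameters()}
        cfg = TrainConfig(stage1_epochs=1, stage2_epochs=0, seed=2)
        train_two_stage(net, x, y, ["a", "b", "c"], cfg)
        for p in net.backbone_parameters():
            assert np.array_equal(p.data, before[id(p)])

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        x = rng.random((12, 3, 64, 64))
        y = np.repeat([0, 1, 2], 4)

        def run():
            net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=9)
            cfg = TrainConfig(stage1_epochs=1, stage2_epochs=1, seed=9)
            return train_two_stage(net, x, y, ["a", "b", "c"], cfg).net.state_arrays()

        a, b = run(), run()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_l2_regularization_shrinks_parameter_norm(self):
        rng = np.random.default_rng(3)
        x = rng.random((12, 3, 64, 64))
        y = np.repeat([0, 1, 2], 4)

        def norm_after(lam):
            net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=4)
            cfg = TrainConfig(stage1_epochs=1, stage2_epochs=1, weight_decay=lam, seed=4)
            trained = train_two_stage(net, x, y, ["a", "b", "c"], cfg)
            return np.sqrt(sum(np.sum(p.data ** 2) for p in trained.net.parameters()))

        assert norm_after(1e-2) <= norm_after(0.0)

    def test_empty_training_set_rejected(self):
        net = build_network(BackboneConfig(variant="tiny", input_size=64), 3, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_two_stage(net, np.empty((0, 3, 64, 64)), np.array([]),
                            ["a", "b", "c"], TrainConfig())

    def test_reported_loss_matches_independent_formula(self, trained_small):
        """Mean cross-entropy + lambda*||theta||^2, evaluated from scratch,
        agrees with the training loop's loss computation on one batch."""
        trained, x, y, _ = trained_small
        from spermvision.network import loss_with_l2

        net = trained.net
        net.eval()
        logits = net.forward(x[:16])["logits"]
        params = net.parameters()
        lam = trained.train_config.weight_decay
        _, loop_loss = loss_with_l2(logits, y[:16], params, lam)
        # independent evaluation: explicit softmax NLL plus explicit penalty
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        ce = -np.mean(np.log(p[np.arange(16), y[:16]]))
        l2 = lam * sum(float(np.sum(q.data ** 2)) for q in params)
        assert abs(loop_loss - (ce + l2)) < 1e-6

    def test_batch_prediction_equals_per_image(self, trained_small):
        trained, x, _, _ = trained_small
        batch_labels, _ = predict(trained, x[:6])
        single = np.concatenate([predict(trained, x[i:i + 1])[0] for i in range(6)])
        assert np.array_equal(batch_labels, single)

    def test_trained_accuracy_above_chance(self, trained_small):
        trained, x, y, _ = trained_small
        labels, _ = predict(trained, x)
        assert np.mean(labels == y) > 1 / 3


class TestSplitAndCheckpoint:
    def test_stratified_split_fractions(self):
        y = np.repeat([0, 1, 2], 60)
        tr, val, te = stratified_split(y, (0.7, 0.15, 0.15), 0)
        assert len(tr) == 126 and len(val) == 27 and len(te) == 27
        assert set(tr) | set(val) | set(te) == set(range(180))

    def test_checkpoint_round_trip(self, tmp_path, trained_small):
        trained, x, _, _ = trained_small
        save_checkpoint(trained, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        p1, _ = predict(trained, x[:4])
        p2, _ = predict(back, x[:4])
        assert np.array_equal(p1, p2)
        assert back.class_names == trained.class_names
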