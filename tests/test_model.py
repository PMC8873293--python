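"""Dual-head 3D U-Net: construction, losses, schedule, gradients, training."""

import numpy as np
import pytest

from couinaud3d import nn
from couinaud3d.grid import LabelMap, VolumeGrid
from couinaud3d.model import (
    ModelConfig,
    ShapeError,
    TrainConfig,
    boundary_target,
    build_network,
    dice_loss,
    lr_at_epoch,
    predict,
    sigmoid,
    softmax,
    softmax_dice_grad,
    train,
)
from couinaud3d.preprocessing import PreprocessConfig

from conftest import small_config


TINY = ModelConfig(base_channels=2, depth=2, coord_channels=False)


class TestBuildNetwork:
    def test_output_shapes_match_input(self):
        net = build_network(ModelConfig(base_channels=2, depth=3, coord_channels=False), seed=0)
        x = np.random.default_rng(0).standard_normal((1, 1, 32, 32, 32)).astype(np.float32)
        seg, bnd = net.forward(x, train=False)
        assert seg.shape == (1, 9, 32, 32, 32)
        assert bnd.shape == (1, 1, 32, 32, 32)

    def test_softmax_probabilities_sum_to_one(self):
        net = build_network(TINY, seed=0)
        x = np.random.default_rng(1).standard_normal((2, 1, 8, 8, 8)).astype(np.float32)
        seg, _ = net.forward(x, train=False)
        np.testing.assert_allclose(softmax(seg).sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initial_parameters(self):
        a = build_network(TINY, seed=7)
        b = build_network(TINY, seed=7)
        for (na, la, ka), (nb, lb, kb) in zip(a.named_params(), b.named_params()):
            assert na == nb
            np.testing.assert_array_equal(la.params[ka], lb.params[kb])

    def test_indivisible_patch_raises(self):
        net = build_network(ModelConfig(base_channels=2, depth=3, coord_channels=False), seed=0)
        x = np.zeros((1, 1, 10, 10, 10), dtype=np.float32)
        with pytest.raises(ShapeError):
            net.forward(x)


class TestBoundaryTarget:
    def test_solid_cube_shell(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[2:7, 2:7, 2:7] = True
        shell = boundary_target(m)
        assert shell.sum() == 5**3 - 3**3
        assert (shell <= m).all()

    def test_empty_mask_empty_shell(self):
        assert boundary_target(np.zeros((4, 4, 4), dtype=bool)).sum() == 0


class TestDiceLoss:
    def _onehot(self, labels, classes=9):
        out = np.zeros((labels.shape[0], classes, *labels.shape[1:]), dtype=np.float32)
        for c in range(classes):
            out[:, c] = labels == c
        return out

    def test_perfect_prediction_near_zero(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 9, (1, 6, 6, 6))
        onehot = self._onehot(t)
        loss, _ = dice_loss(onehot, onehot)
        assert loss < 1e-4

    def test_inverted_binary_prediction_near_one(self):
        t = np.zeros((1, 1, 4, 4, 4), dtype=np.float32)
        t[0, 0, :2] = 1
        loss, _ = dice_loss(1.0 - t, t, foreground_only=False)
        assert loss == pytest.approx(1.0, abs=1e-3)

    def test_uniform_prediction_on_balanced_target(self):
        # 9 classes, 9 voxels per class, p = 1/9 everywhere:
        # per class dice = (2 * 9/9 + eps) / (81/9 + 9 + eps) = 2/18 = 1/9
        labels = np.arange(81).reshape(1, 81, 1, 1) // 9
        onehot = self._onehot(labels)
        probs = np.full_like(onehot, 1.0 / 9.0)
        loss, _ = dice_loss(probs, onehot)
        eps = 1e-5
        n = 81 / 9
        expected = 1.0 - (2 * n / 9 + eps) / (n + n + eps)
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_loss_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = softmax(rng.standard_normal((1, 9, 4, 4, 4)))
            t = self._onehot(rng.integers(0, 9, (1, 4, 4, 4)))
            loss, _ = dice_loss(p, t)
            assert -1e-9 <= loss <= 1.0 + 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            dice_loss(np.zeros((1, 9, 4, 4, 4)), np.zeros((1, 9, 4, 4, 2)))


class TestLrSchedule:
    def test_step_decay_schedule_values(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 0) == pytest.approx(1e-3, rel=1e-12)
        assert lr_at_epoch(cfg, 49) == pytest.approx(1e-3, rel=1e-12)
        assert lr_at_epoch(cfg, 50) == pytest.approx(1e-4, rel=1e-12)
        assert lr_at_epoch(cfg, 100) == pytest.approx(1e-5, rel=1e-12)
        assert lr_at_epoch(cfg, 149) == pytest.approx(1e-5, rel=1e-12)

    def test_epoch_out_of_range_raises(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, 150)
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, -1)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Full dual-head network gradient check in float64."""
        rng = np.random.default_rng(0)
        net = build_network(ModelConfig(base_channels=2, depth=2, coord_channels=False),
                            seed=1, dtype=np.float64)
        # zero-init heads would null the first gradients; perturb them
        for head in (net.seg_head, net.bnd_head):
            head.params["W"] += rng.standard_normal(head.params["W"].shape) * 0.1
        x = rng.standard_normal((2, 1, 4, 4, 4))
        t = rng.integers(0, 9, (2, 4, 4, 4))
        onehot = np.zeros((2, 9, 4, 4, 4))
        for c in range(9):
            onehot[:, c] = t == c
        bnd_t = (rng.random((2, 1, 4, 4, 4)) < 0.3).astype(float)

        def loss_value():
            seg, bnd = net.forward(x, train=True)
            l1, _ = dice_loss(softmax(seg), onehot)
            l2, _ = dice_loss(sigmoid(bnd), bnd_t, foreground_only=False)
            return l1 + l2

        seg, bnd = net.forward(x, train=True)
        p = softmax(seg)
        _, dp = dice_loss(p, onehot)
        pb = sigmoid(bnd)
        _, dpb = dice_loss(pb, bnd_t, foreground_only=False)
        net.backward(softmax_dice_grad(p, dp), dpb * pb * (1 - pb))

        eps = 1e-6
        worst = 0.0
        for name, layer, key in net.named_params():
            flat = layer.params[key].reshape(-1)
            grad = layer.grads[key].reshape(-1)
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_value()
                flat[i] = old - eps
                lm = loss_value()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                rel = abs(num - grad[i]) / max(1e-8, abs(num) + abs(grad[i]))
                worst = max(worst, rel)
        assert worst < 1e-5


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_run(self):
        from couinaud3d.phantom import generate_case

        cases = [generate_case(small_config(seed=s)) for s in range(3)]
        mcfg = ModelConfig(base_channels=4, depth=2)
        tcfg = TrainConfig(
            lr_initial=0.5, lr_decay_every_epochs=10, epochs=4, batch_size=2,
            patch_shape=(32, 32, 32), patches_per_case=2, seed=0,
        )
        pcfg = PreprocessConfig(target_spacing_mm=(2.0, 2.0, 3.0), patch_shape=(32, 32, 32))
        net, hist = train(cases, mcfg, tcfg, pcfg)
        return cases, net, hist, (mcfg, tcfg, pcfg)

    def test_loss_decreases(self, tiny_run):
        _, _, hist, _ = tiny_run
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_batch_larger_than_dataset_handled(self):
        from couinaud3d.phantom import generate_case

        cases = [generate_case(small_config(seed=9))]
        tcfg = TrainConfig(lr_initial=0.1, epochs=1, batch_size=4,
                           patch_shape=(32, 32, 32), patches_per_case=1, seed=0)
        pcfg = PreprocessConfig(target_spacing_mm=(2.0, 2.0, 3.0), patch_shape=(32, 32, 32))
        _, hist = train(cases, ModelConfig(base_channels=2, depth=2), tcfg, pcfg)
        assert len(hist) == 1

    def test_same_seed_identical_history(self):
        from couinaud3d.phantom import generate_case

        cases = [generate_case(small_config(seed=s)) for s in range(2)]
        mcfg = ModelConfig(base_channels=2, depth=2)
        tcfg = TrainConfig(lr_initial=0.2, epochs=2, batch_size=1,
                           patch_shape=(32, 32, 32), patches_per_case=1, seed=3)
        pcfg = PreprocessConfig(target_spacing_mm=(2.0, 2.0, 3.0), patch_shape=(32, 32, 32))
        _, h1 = train(cases, mcfg, tcfg, pcfg)
        _, h2 = train(cases, mcfg, tcfg, pcfg)
        assert h1 == h2

    def test_predict_native_shape_and_argmax(self, tiny_run):
        cases, net, _, (mcfg, tcfg, pcfg) = tiny_run
        case = cases[0]
        labels, probs = predict(case.image, net, pcfg, patch_shape=(32, 32, 32))
        assert labels.shape == case.image.shape
        assert set(np.unique(labels.data)) <= set(range(9))
        np.testing.assert_array_equal(
            np.asarray(labels.data), np.argmax(probs, axis=0).astype(np.int16)
        )

    def test_checkpoint_round_trip(self, tiny_run, tmp_path):
        from couinaud3d.model import load_checkpoint, save_checkpoint

        cases, net, _, (mcfg, tcfg, pcfg) = tiny_run
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        net2 = load_checkpoint(path)
        x = np.random.default_rng(0).standard_normal(
            (1, mcfg.in_channels, 16, 16, 16)
        ).astype(np.float32)
        s1, _ = net.forward(x, train=False)
        s2, _ = net2.forward(x, train=False)
        np.testing.assert_allclose(s1, s2, atol=1e-6)
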