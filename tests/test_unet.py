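import numpy as np
import pytest

from bdseg.phantom import make_phantom
from bdseg.unet import (
    LRSchedule,
    UNetConfig,
    build_unet,
    predict_proba,
    prepare_input,
    threshold_and_fill,
    train_unet,
)
from bdseg.unet.train import bce_loss, dice_loss
from bdseg.volumes import ProbabilityMap

from conftest import small_spec


def expected_param_count(depth, base, in_ch=2):
    """Closed-form layer-by-layer parameter count."""
    ch = [base * 2 ** i for i in range(depth)]
    total = 0

    def conv(ci, co, k):
        return co * ci * k ** 3 + co

    def bn(c):
        return 2 * c

    c_prev = in_ch
    for c in ch:  # encoder blocks
        total += conv(c_prev, c, 3) + bn(c) + conv(c, c, 3) + bn(c)
        c_prev = c
    for i in range(depth - 2, -1, -1):  # decoder
        total += ch[i + 1] * ch[i] * 8 + ch[i]  # transposed conv 2^3
        total += conv(2 * ch[i], ch[i], 3) + bn(ch[i])
        total += conv(ch[i], ch[i], 3) + bn(ch[i])
    total += conv(ch[0], 1, 1)  # head
    return total


class TestBuildUnet:
    def test_param_count_depth2_base8(self):
        net = build_unet(UNetConfig(depth=2, base_channels=8))
        assert net.num_parameters() == expected_param_count(2, 8)

    def test_param_count_depth3_base4(self):
        net = build_unet(UNetConfig(depth=3, base_channels=4))
        assert net.num_parameters() == expected_param_count(3, 4)

    def test_output_shape_and_channels(self):
        net = build_unet(UNetConfig(depth=2, base_channels=4))
        out = net.forward(np.zeros((1, 2, 8, 12, 16)), train=False)
        assert out.shape == (1, 1, 8, 12, 16)

    def test_zero_input_finite_probabilities(self):
        net = build_unet(UNetConfig(depth=2, base_channels=4))
        out = net.forward(np.zeros((1, 2, 8, 8, 8)), train=False)
        assert np.all(np.isfinite(out))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_indivisible_shape_errors(self):
        net = build_unet(UNetConfig(depth=3, base_channels=4))
        with pytest.raises(ValueError, match="pad"):
            net.forward(np.zeros((1, 2, 10, 8, 8)))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=1)
        with pytest.raises(ValueError):
            UNetConfig(base_channels=2)
        with pytest.raises(ValueError):
            UNetConfig(lr_initial=1e-6, lr_floor=1e-5)

    def test_relu_sigmoid_variant_floors_at_half(self):
        net = build_unet(UNetConfig(depth=2, base_channels=4,
                                    final_activation="relu_sigmoid"))
        out = net.forward(np.zeros((1, 2, 8, 8, 8)), train=False)
        assert out.min() >= 0.5


class TestGradients:
    def test_full_network_gradcheck(self):
        cfg = UNetConfig(depth=2, base_channels=4, seed=0)
        net = build_unet(cfg)
        rng = np.random.default_rng(1)
        x = rng.random((1, 2, 4, 4, 4))
        y = (rng.random((1, 1, 4, 4, 4)) > 0.5).astype(float)
        prob = net.forward(x, train=True)
        loss, dprob = dice_loss(prob, y)
        net.backward(dprob)
        layers = [l for l in net.layers() if l.params]
        for layer in (layers[0], layers[len(layers) // 2], layers[-1]):
            for key, w in layer.params.items():
                idx = tuple(np.unravel_index(rng.integers(w.size), w.shape))
                eps = 1e-6
                orig = w[idx]
                w[idx] = orig + eps
                lp, _ = dice_loss(net.forward(x, train=True), y)
                w[idx] = orig - eps
                lm, _ = dice_loss(net.forward(x, train=True), y)
                w[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = layer.grads[key][idx]
                assert abs(num - ana) < 1e-6 + 1e-4 * abs(num)


class TestLosses:
    def test_dice_loss_perfect(self):
        p = np.ones((1, 1, 2, 2, 2))
        loss, _ = dice_loss(p, p.copy())
        assert loss < 1e-6

    def test_bce_matches_formula(self, rng):
        p = np.clip(rng.random((1, 1, 2, 2, 2)), 0.01, 0.99)
        g = (rng.random((1, 1, 2, 2, 2)) > 0.5).astype(float)
        loss, _ = bce_loss(p, g)
        ref = -(g * np.log(p) + (1 - g) * np.log(1 - p)).mean()
        np.testing.assert_allclose(loss, ref, rtol=1e-9)


class TestLRSchedule:
    def test_decay_after_patience(self):
        s = LRSchedule(lr_initial=1e-3, factor=0.33, patience=50, floor=1e-5,
                       early_stop=200)
        s.update(1.0)  # improvement epoch
        lrs = [s.update(1.0)[0] for _ in range(50)]
        assert lrs[48] == 1e-3
        np.testing.assert_allclose(lrs[49], 0.33e-3)

    def test_floor(self):
        s = LRSchedule(lr_initial=1e-3, factor=0.33, patience=1, floor=1e-5,
                       early_stop=10_000)
        s.update(1.0)
        for _ in range(100):
            lr, _, _ = s.update(1.0)
        assert lr == 1e-5

    def test_early_stop_exactly_200_after_improvement(self):
        s = LRSchedule(lr_initial=1e-3, factor=0.33, patience=50, floor=1e-5,
                       early_stop=200)
        s.update(1.0)
        stops = [s.update(1.0)[2] for _ in range(200)]
        assert not any(stops[:199])
        assert stops[199]


@pytest.fixture(scope="module")
def tiny_data():
    data = []
    for seed in range(10):
        fw, truth = make_phantom(small_spec(seed=seed))
        data.append((prepare_input(fw), truth.breast_mask.astype(float),
                     fw, truth))
    return data


class TestTraining:
    def test_smoke_training_improves(self, tiny_data):
        train = [(x, y) for x, y, _, _ in tiny_data[:8]]
        val = [(x, y) for x, y, _, _ in tiny_data[8:]]
        cfg = UNetConfig(depth=2, base_channels=4, seed=0, lr_initial=3e-3)
        net = build_unet(cfg)
        state = train_unet(net, train, val, cfg, max_epochs=8)
        assert state.best_val_loss < state.history[0]["val_loss"]

    def test_stub_schedule_semantics(self):
        # constant stub validation loss: lr decays at epoch 50, stop at 200
        cfg = UNetConfig(depth=2, base_channels=4, seed=0, lr_initial=1e-3)
        net = build_unet(cfg)
        rng = np.random.default_rng(0)
        sample = (rng.random((2, 4, 4, 4)), np.zeros((4, 4, 4)))
        state = train_unet(net, [sample], [sample], cfg, max_epochs=300,
                           val_loss_fn=lambda epoch: 1.0)
        lrs = [h["lr"] for h in state.history]
        assert lrs[48] == 1e-3
        np.testing.assert_allclose(lrs[50], 0.33e-3)
        assert min(lrs) >= 1e-5
        assert state.stopped_early
        # improvement at epoch 0 (inf -> 1.0), stop 200 stale epochs later
        assert state.epoch == 200

    def test_empty_sets_error(self):
        cfg = UNetConfig(depth=2, base_channels=4)
        net = build_unet(cfg)
        with pytest.raises(ValueError, match="non-empty"):
            train_unet(net, [], [], cfg)


class TestPredict:
    def test_range_and_determinism(self, tiny_data):
        net = build_unet(UNetConfig(depth=2, base_channels=4, seed=1))
        fw = tiny_data[0][2]
        p1 = predict_proba(net, fw)
        p2 = predict_proba(net, fw)
        assert p1.data.min() >= 0 and p1.data.max() <= 1
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_separation_after_smoke_training(self, tiny_data):
        train = [(x, y) for x, y, _, _ in tiny_data[:8]]
        val = [(x, y) for x, y, _, _ in tiny_data[8:]]
        cfg = UNetConfig(depth=2, base_channels=4, seed=0, lr_initial=3e-3)
        net = build_unet(cfg)
        train_unet(net, train, val, cfg, max_epochs=10)
        fw, truth = tiny_data[9][2], tiny_data[9][3]
        pm = predict_proba(net, fw)
        inside = pm.data[truth.breast_mask.astype(bool)].mean()
        outside = pm.data[~truth.breast_mask.astype(bool)].mean()
        assert inside > outside


class TestThresholdAndFill:
    def test_threshold_semantics_at_035(self):
        data = np.zeros((1, 2, 2))
        data[0, 0, 0] = 0.36
        data[0, 0, 1] = 0.34
        mask = threshold_and_fill(ProbabilityMap(data), thr=0.35)
        assert mask.data[0, 0, 0] == 1
        assert mask.data[0, 0, 1] == 0

    def test_cavity_filled(self):
        data = np.zeros((1, 8, 8))
        data[0, 1:7, 1:7] = 0.9
        data[0, 3:5, 3:5] = 0.0  # interior cavity
        mask = threshold_and_fill(ProbabilityMap(data))
        assert mask.data[0, 3, 3] == 1

    def test_all_zero_map(self):
        mask = threshold_and_fill(ProbabilityMap(np.zeros((2, 4, 4))))
        assert not mask.data.any()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            threshold_and_fill(ProbabilityMap(np.zeros((2, 2, 2))), thr=1.5)

    def test_monotone_in_threshold(self, rng):
        p = ProbabilityMap(rng.random((2, 6, 6)))
        low = (p.data > 0.3)
        high = (p.data > 0.6)
        assert np.all(high <= low)
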