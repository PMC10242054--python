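"""Loss definitions, optimiser behaviour, and the spatial-only gradient
semantics that distinguish the two backprop regimes."""

import numpy as np
import pytest

import vtsnn._autodiff as ad
from vtsnn import (Adam, BackpropMode, NeuronConfig, NetworkSpec, TrainConfig,
                   build_uvtsnn, evaluate, fit, itbp_loss, psnr, stbp_loss,
                   train_step, uwe_encode)
from vtsnn.network import _ConvSpike
from vtsnn.training import _plane_weights, decode_weighted_sum, encode_batch


class TestItbpLoss:
    def test_identical_stacks_give_zero(self, rng):
        planes = (rng.random((8, 5, 5)) < 0.5).astype(float)
        rep = itbp_loss(planes, planes, N=1)
        assert rep.total == 0.0

    @pytest.mark.parametrize("significance", range(8))
    def test_single_flipped_bit_costs_two_to_the_significance(self, significance):
        a = np.zeros((8, 3, 3))
        b = a.copy()
        b[7 - significance, 1, 1] = 1  # storage is MSB first
        assert itbp_loss(a, b, N=1).total == 2 ** significance

    def test_fully_flipped_pixel_costs_255(self):
        a = np.zeros((8, 2, 2))
        b = a.copy()
        b[:, 0, 0] = 1
        assert itbp_loss(a, b, N=1).total == 255.0

    def test_per_plane_breakdown_sums_to_total_times_N(self, rng):
        a = (rng.random((8, 4, 4)) < 0.5).astype(float)
        b = (rng.random((8, 4, 4)) < 0.5).astype(float)
        rep = itbp_loss(a, b, N=4)
        assert rep.per_plane.sum() == pytest.approx(rep.total * 4)

    def test_doubling_significance_doubles_contribution(self):
        for s in range(7):
            lo = np.zeros((8, 1, 1)); hi = np.zeros((8, 1, 1))
            lo[7 - s, 0, 0] = 1
            hi[7 - (s + 1), 0, 0] = 1
            assert itbp_loss(np.zeros((8, 1, 1)), hi).total == \
                2 * itbp_loss(np.zeros((8, 1, 1)), lo).total

    def test_mismatched_T_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            itbp_loss(np.zeros((8, 2, 2)), np.zeros((4, 2, 2)))


class TestStbpLoss:
    def test_equal_images_give_zero(self):
        y = np.arange(4).reshape(2, 2)
        assert stbp_loss(y, y.astype(float)).total == 0.0

    def test_unit_difference_on_2x2_gives_four(self):
        y = np.zeros((2, 2))
        assert stbp_loss(y, np.ones((2, 2))).total == 4.0

    def test_matches_element_loop_oracle(self, rng):
        y = rng.integers(0, 256, (3, 3)).astype(float)
        yhat = rng.normal(128, 40, (3, 3))
        expected = sum((y[i, j] - yhat[i, j]) ** 2
                       for i in range(3) for j in range(3))
        assert stbp_loss(y, yhat, N=2).total == pytest.approx(expected / 2)


class TestEncodeDecodeHelpers:
    def test_encode_batch_matches_per_image_codec(self, rng):
        imgs = rng.integers(0, 256, size=(3, 8, 8))
        batch = encode_batch(imgs, 8)
        for i, img in enumerate(imgs):
            assert np.array_equal(batch[:, i, :, :, 0], uwe_encode(img).planes)

    def test_weighted_sum_decode_matches_codec_weights(self, rng):
        planes = (rng.random((8, 2, 4, 4, 1)) < 0.4).astype(float)
        outs = [ad.Tensor(p) for p in planes]
        dec = decode_weighted_sum(outs, 8)
        manual = (ast := _plane_weights(8))[:, None, None, None, None] * planes
        assert np.allclose(dec.data, manual.sum(axis=0))


def _toy_layers(seed=0):
    """Two spiking conv layers, the smallest network with a hidden layer."""
    rng = np.random.default_rng(seed)
    return [_ConvSpike(rng, 1, 2, 3, 1, NeuronConfig(v_threshold=1.0), "l1"),
            _ConvSpike(rng, 2, 1, 3, 1, NeuronConfig(v_threshold=0.077), "l2")]


def _joint_detached_grads(layers, xseq, target, weights):
    """Forward T steps with inter-step state detached; one joint backward."""
    for l in layers:
        l.weight.zero_grad()
    states = [None] * len(layers)
    stored = []  # membrane values entering each step, per layer
    loss = None
    for t, x in enumerate(xseq):
        stored.append([None if s is None else np.array(s.data) for s in states])
        h = ad.Tensor(x)
        new_states = []
        for li, l in enumerate(layers):
            s, u = l.step(h, states[li])
            new_states.append(ad.detach(u))
            h = s
        states = new_states
        term = ad.scale(ad.tsum(ad.square(ad.sub(h, ad.Tensor(target[t])))), weights[t])
        loss = term if loss is None else ad.add(loss, term)
    loss.backward()
    return [np.array(l.weight.grad) for l in layers], stored


def _per_step_grads(layers, xseq, target, weights, stored):
    """Oracle: rebuild each step from its stored entry state as constants,
    backpropagate that step's loss alone, accumulate over steps."""
    acc = [np.zeros_like(l.weight.data) for l in layers]
    for t, x in enumerate(xseq):
        for l in layers:
            l.weight.zero_grad()
        h = ad.Tensor(x)
        for li, l in enumerate(layers):
            entry = stored[t][li]
            s, _ = l.step(h, None if entry is None else ad.Tensor(entry))
            h = s
        loss_t = ad.scale(ad.tsum(ad.square(ad.sub(h, ad.Tensor(target[t])))), weights[t])
        loss_t.backward()
        for li, l in enumerate(layers):
            if l.weight.grad is not None:
                acc[li] += l.weight.grad
    return acc


class TestTemporalIndependence:
    """Severing inter-step state makes the T-step gradient exactly the sum
    of per-step gradients — spatial-only credit assignment."""

    def test_detached_joint_gradients_equal_per_step_recomputation(self, rng):
        layers = _toy_layers(seed=1)
        T = 4
        xseq = (rng.random((T, 2, 8, 8, 1)) < 0.4).astype(float)
        target = (rng.random((T, 2, 8, 8, 1)) < 0.4).astype(float)
        weights = _plane_weights(T)
        joint, stored = _joint_detached_grads(layers, xseq, target, weights)
        oracle = _per_step_grads(layers, xseq, target, weights, stored)
        for g_joint, g_oracle in zip(joint, oracle):
            denom = max(np.abs(g_oracle).max(), 1e-12)
            assert np.abs(g_joint - g_oracle).max() / denom <= 1e-6

    def test_forward_spikes_identical_with_and_without_detach(self, tiny_model, rng):
        stack = (rng.random((8, 1, 16, 16, 1)) < 0.3).astype(float)
        on = tiny_model.forward_tensor(stack, detach_time=True)
        off = tiny_model.forward_tensor(stack, detach_time=False)
        for a, b in zip(on, off):
            assert np.array_equal(a.data, b.data)


class TestTrainStep:
    @pytest.mark.parametrize("mode", ["ITBP", "STBP"])
    def test_zero_learning_rate_leaves_parameters_unchanged(self, mode, small_bundle):
        model = build_uvtsnn(NetworkSpec(depth=1, base_channels=4), seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        clean, noisy = small_bundle.arrays()
        cfg = TrainConfig(mode=mode, learning_rate=0.0, batch_size=8)
        train_step(model, noisy, clean, cfg)
        for k, v in model.state_dict().items():
            assert np.array_equal(before[k], v)

    def test_overfit_one_batch_reduces_itbp_loss(self, small_bundle):
        model = build_uvtsnn(NetworkSpec(depth=1, base_channels=4), seed=0)
        clean, noisy = small_bundle.arrays()
        clean, noisy = clean[:4], noisy[:4]
        cfg = TrainConfig(mode="ITBP", batch_size=4)
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        first = train_step(model, noisy, clean, cfg, opt).total
        last = None
        for _ in range(60):
            last = train_step(model, noisy, clean, cfg, opt).total
        assert last < first

    def test_shape_mismatch_rejected(self, tiny_model):
        cfg = TrainConfig()
        with pytest.raises(ValueError, match="mismatch"):
            train_step(tiny_model, np.zeros((2, 16, 16), int),
                       np.zeros((2, 8, 8), int), cfg)


class TestFitAndEvaluate:
    def test_seeded_fit_is_reproducible(self, small_bundle):
        clean, noisy = small_bundle.arrays()
        losses = []
        for _ in range(2):
            model = build_uvtsnn(NetworkSpec(depth=1, base_channels=4), seed=0)
            cfg = TrainConfig(mode="ITBP", epochs=2, batch_size=4, seed=9)
            hist = fit(model, clean, noisy, cfg)
            losses.append([h["mean_loss"] for h in hist])
        assert losses[0] == losses[1]

    def test_evaluate_reports_per_image_psnr_and_never_mutates(self, tiny_model, small_bundle):
        clean, noisy = small_bundle.arrays()
        before = {k: v.copy() for k, v in tiny_model.state_dict().items()}
        reports = evaluate(tiny_model, clean, noisy)
        assert len(reports) == len(clean)
        assert all(np.isfinite(r.psnr) or r.capped for r in reports)
        for k, v in tiny_model.state_dict().items():
            assert np.array_equal(before[k], v)

    def test_identity_stub_yields_capped_psnr_at_zero_noise(self, small_bundle):
        # codec round trip with no network: PSNR must cap at infinity
        clean, _ = small_bundle.arrays()
        rep = psnr(clean[0], clean[0])
        assert rep.capped

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            evaluate(tiny_model, np.zeros((0, 16, 16)), np.zeros((0, 16, 16)))

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(mode="BPTT")
        assert TrainConfig(mode="STBP").mode is BackpropMode.STBP
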