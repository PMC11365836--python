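"""Losses, gradient routing, the dual-task loop, and model selection."""

import numpy as np
import pytest

from ivdseg import (NetworkSpec, TrainConfig, TransformParams, build_model,
                    dice_loss, predict, pretext_loss, sample_pretext, train,
                    train_step)
from ivdseg.nn import Adam
from ivdseg.phantom import DomainSample
from ivdseg.training import LossRecord


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self, rng):
        y = (rng.random((8, 8, 4)) > 0.6).astype(np.uint8)
        assert dice_loss(y.astype(np.float32), y) < 1e-4

    def test_disjoint_prediction_is_one(self):
        y = np.zeros((8, 8, 4), np.uint8)
        y[:4] = 1
        pred = 1.0 - y.astype(np.float32)
        assert dice_loss(pred, y) > 1 - 1e-4

    def test_uniform_half_closed_form(self):
        # p = 0.5 everywhere, foreground fraction f:
        # loss = 1 - f/(0.5+f); at f = 1/4 this is 1 - (1/4)/(3/4) = 2/3
        y = np.zeros((8, 8, 4), np.uint8)
        y[:2] = 1  # exactly 1/4 foreground
        pred = np.full(y.shape, 0.5, np.float32)
        assert dice_loss(pred, y) == pytest.approx(2 / 3, abs=1e-4)

    def test_invalid_inputs_rejected(self):
        y = np.zeros((4, 4, 2), np.uint8)
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4, 3), np.float32), y)
        with pytest.raises(ValueError):
            dice_loss(np.full((4, 4, 2), 1.5, np.float32), y)
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4, 2), np.float32),
                      np.full((4, 4, 2), 2, np.uint8))


class TestPretextLoss:
    def test_one_hot_is_zero(self):
        assert pretext_loss(np.array([0, 0, 1, 0], np.float32), 2) \
            == pytest.approx(0.0, abs=1e-4)

    def test_uniform_is_log4(self):
        p = np.full(4, 0.25, np.float32)
        assert pretext_loss(p, 1) == pytest.approx(np.log(4), abs=1e-4)

    def test_batch_mean(self):
        p = np.array([[0.5, 0.5, 0.0, 0.0], [0.25, 0.25, 0.25, 0.25]],
                     np.float32)
        a = -np.log(0.5)
        b = -np.log(0.25)
        assert pretext_loss(p, [0, 3]) == pytest.approx((a + b) / 2, rel=1e-5)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            pretext_loss(np.full(4, 0.25, np.float32), 7)

    def test_zero_probability_floored(self):
        loss = pretext_loss(np.array([1.0, 0.0, 0.0, 0.0], np.float32), 1)
        assert np.isfinite(loss)


def _tiny_setup(tiny_dataset, tiny_net_spec, w_seg=1.0, w_p=1.0,
                baseline=False):
    config = TrainConfig(
        epochs=1, seed=0, loss_weights=(w_seg, w_p),
        pretext_domains=() if baseline else ("S",),
        pretext_kinds=() if baseline else ("intensity",))
    model = build_model(tiny_net_spec, init_seed=0)
    opt = Adam(model.params(), lr=1e-3)
    params = TransformParams(rng_seed=1)
    seg_batch = [tiny_dataset[0]]
    pretext = None
    if not baseline:
        pretext = {"intensity": [sample_pretext(tiny_dataset[i], params, i)
                                 for i in range(4)]}
    return model, opt, config, seg_batch, pretext


def _param_values(params):
    return [p.value.copy() for p in params]


def _changed(before, params):
    return any(not np.array_equal(b, p.value)
               for b, p in zip(before, params))


class TestTrainStep:
    def test_gradient_routing_seg_zeroed(self, tiny_dataset, tiny_net_spec):
        """With L_seg weight zero, the pretext gradient must reach encoder
        and head but never the decoder."""
        model, opt, cfg, seg, pre = _tiny_setup(tiny_dataset, tiny_net_spec,
                                                w_seg=0.0)
        enc0 = _param_values(model.encoder_params())
        dec0 = _param_values(model.decoder_params())
        head0 = _param_values(model.head_params())
        train_step(model, seg, pre, cfg, opt)
        assert _changed(enc0, model.encoder_params())
        assert _changed(head0, model.head_params())
        assert not _changed(dec0, model.decoder_params())

    def test_gradient_routing_pretext_zeroed(self, tiny_dataset,
                                             tiny_net_spec):
        model, opt, cfg, seg, pre = _tiny_setup(tiny_dataset, tiny_net_spec,
                                                w_p=0.0)
        enc0 = _param_values(model.encoder_params())
        dec0 = _param_values(model.decoder_params())
        head0 = _param_values(model.head_params())
        train_step(model, seg, pre, cfg, opt)
        assert _changed(enc0, model.encoder_params())
        assert _changed(dec0, model.decoder_params())
        assert not _changed(head0, model.head_params())

    def test_loss_additivity(self, tiny_dataset, tiny_net_spec):
        model, opt, cfg, seg, pre = _tiny_setup(tiny_dataset, tiny_net_spec)
        rec = train_step(model, seg, pre, cfg, opt)
        assert rec.l_total == pytest.approx(rec.l_seg + rec.l_p, abs=1e-6)

    def test_deterministic(self, tiny_dataset, tiny_net_spec):
        recs = []
        for _ in range(2):
            model, opt, cfg, seg, pre = _tiny_setup(tiny_dataset,
                                                    tiny_net_spec)
            recs.append(train_step(model, seg, pre, cfg, opt))
        assert recs[0].l_seg == recs[1].l_seg
        assert recs[0].l_p == recs[1].l_p

    def test_batch_mode_mismatch_rejected(self, tiny_dataset, tiny_net_spec):
        model, opt, cfg, seg, pre = _tiny_setup(tiny_dataset, tiny_net_spec,
                                                baseline=True)
        with pytest.raises(ValueError):
            train_step(model, seg, {"intensity": []} or None, cfg, opt)
        model, opt, cfg, seg, _ = _tiny_setup(tiny_dataset, tiny_net_spec)
        with pytest.raises(ValueError):
            train_step(model, seg, None, cfg, opt)


class TestTrain:
    def test_loss_decreases_on_separable_phantoms(self, tiny_dataset,
                                                  tiny_net_spec):
        for seed in (0, 1, 2):
            cfg = TrainConfig(epochs=5, seed=seed)
            model, hist = train(tiny_dataset[:8], tiny_dataset[8:10], {},
                                cfg, network_spec=NetworkSpec(
                                    base_channels=4, n_encoder_blocks=2,
                                    pretext_heads=()))
            first = np.mean([r.l_seg for r in hist["steps"][:8]])
            last = np.mean([r.l_seg for r in hist["steps"][-8:]])
            assert last < first

    def test_selected_checkpoint_minimises_val_total(self, tiny_dataset,
                                                     tiny_net_spec):
        cfg = TrainConfig(epochs=4, seed=1, pretext_domains=("S",),
                          pretext_kinds=("intensity",))
        _, hist = train(tiny_dataset[:6], tiny_dataset[6:8], {}, cfg,
                        network_spec=tiny_net_spec)
        totals = [r.l_total for r in hist["val"]]
        assert hist["best_epoch"] == int(np.argmin(totals))

    def test_baseline_history_has_no_pretext_loss(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, seed=0)
        _, hist = train(tiny_dataset[:4], tiny_dataset[4:6], {}, cfg,
                        network_spec=NetworkSpec(base_channels=4,
                                                 n_encoder_blocks=2,
                                                 pretext_heads=()))
        assert all(r.l_p is None for r in hist["steps"])
        assert all(r.l_p is None for r in hist["val"])

    def test_reproducible_history(self, tiny_dataset, tiny_net_spec):
        hists = []
        for _ in range(2):
            cfg = TrainConfig(epochs=2, seed=3, pretext_domains=("S",),
                              pretext_kinds=("intensity",))
            _, h = train(tiny_dataset[:4], tiny_dataset[4:6], {}, cfg,
                         network_spec=tiny_net_spec)
            hists.append([(r.l_seg, r.l_p, r.l_total) for r in h["steps"]])
        assert hists[0] == hists[1]

    def test_empty_sets_rejected(self, tiny_dataset, tiny_net_spec):
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train([], tiny_dataset[:2], {}, cfg, network_spec=tiny_net_spec)
        with pytest.raises(ValueError):
            train(tiny_dataset[:2], [], {}, cfg, network_spec=tiny_net_spec)

    def test_unknown_pretext_domain_rejected(self, tiny_dataset,
                                             tiny_net_spec):
        cfg = TrainConfig(epochs=1, pretext_domains=("T9",),
                          pretext_kinds=("intensity",))
        with pytest.raises(ValueError):
            train(tiny_dataset[:2], tiny_dataset[2:4], {}, cfg,
                  network_spec=tiny_net_spec)


class TestPredict:
    def test_output_binary_and_shaped(self, tiny_dataset, tiny_net_spec):
        model = build_model(tiny_net_spec, init_seed=0)
        mask = predict(model, tiny_dataset[0].volume)
        assert mask.shape == tiny_dataset[0].volume.shape
        assert set(np.unique(mask)) <= {0, 1}


def test_loss_record_rejects_non_finite():
    with pytest.raises(ValueError):
        LossRecord(step=0, l_seg=float("nan"), l_p=None, l_total=float("nan"))
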