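"""Joint loss, learning-rate schedule and training-loop behaviour."""

import dataclasses

import numpy as np
import pytest

from hogseg import nn
from hogseg.models import MultiTaskOutput, build_model
from hogseg.training import (
    ABLATION_WEIGHT_GRID,
    LossWeights,
    TrainConfig,
    dataset_hash,
    joint_loss,
    load_checkpoint,
    lr_at,
    sweep,
    train,
)

from .conftest import tiny_model_spec, tiny_train_config


def toy_output(logits, hog_pred):
    return MultiTaskOutput(seg_logits=nn.Tensor(logits),
                           hog_preds=[nn.Tensor(hog_pred)])


class TestJointLoss:
    def hand_example(self, alpha, beta):
        # 1x2-pixel, 2-class toy: logits (0,0) per pixel -> ce = ln 2;
        # head output (0.5, 0.5) vs target (0, 1) -> mse = 0.25
        out = toy_output(np.zeros((1, 2, 1, 2)), np.array([[0.5, 0.5]]))
        mask = np.zeros((1, 1, 2), dtype=int)
        return joint_loss(out, mask, np.array([[0.0, 1.0]]),
                          LossWeights(alpha=alpha, beta=beta))

    def test_hand_computed_example(self):
        total, ce, hog = self.hand_example(1.0, 1.0)
        assert ce == pytest.approx(np.log(2), abs=1e-6)
        assert hog == pytest.approx(0.25, abs=1e-6)
        assert total.item() == pytest.approx(np.log(2) + 0.25, abs=1e-6)

    def test_weight_degeneracies(self):
        total_b0, ce, hog = self.hand_example(1.0, 0.0)
        assert hog == 0.0 and total_b0.item() == ce
        total_a0, _, hog = self.hand_example(0.0, 1.0)
        assert total_a0.item() == 1.0 * hog

    def test_perfect_hog_prediction_zero_loss(self):
        target = np.array([[0.2, 0.8, 0.5]])
        out = toy_output(np.zeros((1, 2, 1, 1)), target.copy())
        _, _, hog = joint_loss(out, np.zeros((1, 1, 1), dtype=int), target,
                               LossWeights())
        assert hog == 0.0

    def test_linearity_in_weights(self):
        t1, _, _ = self.hand_example(0.3, 0.7)
        t2, _, _ = self.hand_example(0.6, 1.4)
        assert t2.item() == pytest.approx(2 * t1.item(), rel=1e-9)

    def test_multiple_heads_averaged(self):
        out = MultiTaskOutput(
            seg_logits=nn.Tensor(np.zeros((1, 2, 1, 1))),
            hog_preds=[nn.Tensor(np.array([[1.0, 0.0]])),
                       nn.Tensor(np.array([[0.0, 0.0]]))])
        _, _, hog = joint_loss(out, np.zeros((1, 1, 1), dtype=int),
                               np.array([[0.0, 0.0]]), LossWeights())
        assert hog == pytest.approx((0.5 + 0.0) / 2)

    def test_length_mismatch_raises(self):
        out = toy_output(np.zeros((1, 2, 1, 1)), np.zeros((1, 5)))
        with pytest.raises(ValueError, match="length"):
            joint_loss(out, np.zeros((1, 1, 1), dtype=int), np.zeros(7),
                       LossWeights())

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)
        with pytest.raises(ValueError):
            LossWeights(alpha=0.0, beta=0.0)


class TestSchedule:
    def test_halving_boundaries(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(2e-4)
        assert lr_at(49_999, cfg) == pytest.approx(2e-4)
        assert lr_at(50_000, cfg) == pytest.approx(1e-4)
        assert lr_at(149_999, cfg) == pytest.approx(5e-5)

    def test_logged_lr_matches_schedule(self, tiny_samples):
        cfg = tiny_train_config(max_iters=40, validate_every=10,
                                decay_every=15)
        res = train(tiny_samples, tiny_model_spec(), cfg)
        for _, row in res.metrics.iterrows():
            assert row["lr"] == pytest.approx(lr_at(int(row["iteration"]) - 1,
                                                    cfg))


class TestTrainLoop:
    def test_deterministic_trajectory(self, tiny_samples):
        spec, cfg = tiny_model_spec(), tiny_train_config()
        a = train(tiny_samples, spec, cfg)
        b = train(tiny_samples, spec, cfg)
        assert a.metrics["total"].tolist() == b.metrics["total"].tolist()

    def test_beta_zero_matches_single_task_backbone(self, tiny_samples):
        cfg = tiny_train_config(
            loss_weights=LossWeights(alpha=1.0, beta=0.0))
        multi = train(tiny_samples, tiny_model_spec(), cfg)
        single = train(tiny_samples, tiny_model_spec(head_placement="none"),
                       cfg)
        assert multi.metrics["total"].tolist() == \
            single.metrics["total"].tolist()
        assert multi.metrics["ce"].tolist() == single.metrics["ce"].tolist()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], tiny_model_spec(), tiny_train_config())

    def test_inconsistent_hog_dim_fails_before_training(self, tiny_samples):
        spec = tiny_model_spec(hog_dim=123)
        with pytest.raises(ValueError, match="pseudo-label length"):
            train(tiny_samples, spec, tiny_train_config())

    def test_checkpoint_roundtrip(self, tiny_samples, tmp_path):
        spec, cfg = tiny_model_spec(), tiny_train_config()
        res = train(tiny_samples, spec, cfg,
                    checkpoint_path=tmp_path / "ck.npz")
        model, meta = load_checkpoint(tmp_path / "ck.npz")
        assert meta["model_spec"]["backbone"] == "unet"
        restored = build_model(spec)
        restored.load_state_dict(res.best_state)
        x = tiny_samples[0].image
        np.testing.assert_array_equal(model.predict_mask(x),
                                      restored.predict_mask(x))


class TestSweep:
    def test_single_cell_equals_direct_train(self, tiny_samples,
                                             tiny_hog_config):
        spec, cfg = tiny_model_spec(), tiny_train_config(max_iters=30,
                                                         validate_every=30)
        table = sweep(tiny_samples, spec, cfg, [(1.0, 1.0)],
                      [tiny_hog_config])
        direct = train(tiny_samples, spec, cfg)
        assert len(table) == 1
        assert table.loc[0, "val_miou"] == pytest.approx(direct.best_miou)
        assert table.loc[0, "hog_dim"] == 504

    def test_ablation_grid_shape_and_split_reuse(self, tiny_samples,
                                                 tiny_hog_config):
        cfg = tiny_train_config(max_iters=5, validate_every=5)
        table = sweep(tiny_samples, tiny_model_spec(), cfg,
                      ABLATION_WEIGHT_GRID, [tiny_hog_config])
        assert len(table) == 5
        assert list(zip(table["alpha"], table["beta"])) == \
            list(ABLATION_WEIGHT_GRID)
        # every cell trained on the identical dataset/split
        assert table["split_hash"].nunique() == 1
        assert table["split_hash"].iloc[0] == dataset_hash(tiny_samples)

    def test_empty_grid_rejected(self, tiny_samples, tiny_hog_config):
        with pytest.raises(ValueError, match="empty"):
            sweep(tiny_samples, tiny_model_spec(), tiny_train_config(),
                  [], [tiny_hog_config])
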