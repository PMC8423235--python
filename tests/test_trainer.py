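"""Training protocol: loss values, seeding, descent, checkpoints, evaluation."""

import math

import numpy as np
import pytest

from hdcnet import _autograd as ag
from hdcnet.data_pipeline import DatasetSpec
from hdcnet.networks import ModelConfig, build_model
from hdcnet.trainer import (
    DATASET_HYPERPARAMS,
    Adam,
    TrainConfig,
    _bce_tensor,
    bce_loss,
    cross_train,
    evaluate,
    load_checkpoint,
    save_checkpoint,
    train,
)

TINY = dict(depth=2, base_channels=8)


class TestBceLoss:
    def test_perfect_prediction_tends_to_zero(self, rng):
        y = (rng.random((5, 5)) > 0.5).astype(float)
        assert bce_loss(y, y) < 1e-5

    def test_uniform_half_gives_ln2(self):
        assert bce_loss(np.full((10, 10), 0.5), np.zeros((10, 10))) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_matches_term_by_term_hand_sum(self):
        prob = np.array([0.9, 0.2, 0.7, 0.4, 0.5])
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])
        expected = -np.mean(
            [np.log(0.9), np.log(0.8), np.log(0.7), np.log(0.4), np.log(0.5)]
        )
        assert bce_loss(prob, y) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_autograd_route_agrees_with_ndarray_route(self, rng):
        prob = rng.uniform(0.01, 0.99, (4, 4))
        y = (rng.random((4, 4)) > 0.5).astype(float)
        assert _bce_tensor(ag.as_tensor(prob), y).data == pytest.approx(
            bce_loss(prob, y), abs=1e-12
        )


class TestPublishedHyperparameters:
    def test_per_dataset_defaults(self):
        assert DATASET_HYPERPARAMS["drive"] == (100, 0.008, 2)
        assert DATASET_HYPERPARAMS["chase_db1"] == (50, 0.008, 2)
        assert DATASET_HYPERPARAMS["stare"] == (80, 0.008, 2)

    def test_default_train_config(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.008 and cfg.batch_size == 2
        assert cfg.model.block.dropblock_block_size == 7
        assert cfg.model.block.dropblock_drop_rate == 0.15


class TestTrain:
    def test_one_epoch_yields_one_record_entry(self, phantom_pairs):
        cfg = TrainConfig(epochs=1, seed=0, validation_fraction=0.0,
                          model=ModelConfig(variant="sd_unet", **TINY))
        record = train(cfg, phantom_pairs[:2])
        assert len(record.epochs) == 1
        assert math.isfinite(record.epochs[0]["train_loss"])

    def test_same_seed_reproduces_first_epoch_loss(self, phantom_pairs):
        cfg = dict(epochs=1, seed=7, validation_fraction=0.0,
                   model=ModelConfig(variant="hdcnet", **TINY))
        a = train(TrainConfig(**cfg), phantom_pairs[:2])
        b = train(TrainConfig(**cfg), phantom_pairs[:2])
        assert a.epochs[0]["train_loss"] == b.epochs[0]["train_loss"]

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train(TrainConfig(), [])

    def test_validation_split_logs_val_metrics(self, phantom_pairs):
        cfg = TrainConfig(epochs=2, seed=0, validation_fraction=0.25,
                          model=ModelConfig(variant="sd_unet", **TINY))
        record = train(cfg, phantom_pairs)
        assert "val_f1" in record.epochs[-1]
        assert record.best_epoch is not None

    def test_tiny_lr_step_never_increases_batch_loss(self, phantom_pairs):
        """First-order descent: a sufficiently small step on one batch cannot
        increase that batch's loss (tolerance 1e-6)."""
        model = build_model(ModelConfig(variant="hdcnet", **TINY), seed=1)
        x = np.stack([p.image.transpose(2, 0, 1) for p in phantom_pairs[:1]])
        y = np.stack([p.mask[None].astype(float) for p in phantom_pairs[:1]])
        loss0 = _bce_tensor(model.forward(ag.as_tensor(x)), y)
        model.zero_grad()
        loss0.backward()
        opt = Adam(model.parameters(), lr=1e-7)
        opt.step()
        loss1 = _bce_tensor(model.forward(ag.as_tensor(x)), y)
        assert loss1.data <= loss0.data + 1e-6


class TestCheckpoints:
    def test_round_trip_reproduces_predictions_bitwise(self, tmp_path, phantom_pairs, rng):
        mcfg = ModelConfig(variant="hdcnet", **TINY)
        model = build_model(mcfg, seed=4)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, mcfg, seed=4, epoch=0)
        loaded, loaded_cfg, meta = load_checkpoint(path)
        assert loaded_cfg == mcfg and meta["epoch"] == 0
        x = ag.as_tensor(rng.random((1, 3, 32, 32)))
        np.testing.assert_array_equal(
            model.forward(x, training=False).data, loaded.forward(x, training=False).data
        )

    def test_unrecognised_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.npz"
        np.savez(bad, __meta__=np.frombuffer(b'{"format": "other"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="checkpoint"):
            load_checkpoint(bad)


class TestEvaluate:
    def test_overfit_model_scores_high_on_training_images(self, phantom_pairs):
        spec = DatasetSpec("phantom", (64, 64), (64, 64))
        cfg = TrainConfig(epochs=12, seed=1, validation_fraction=0.0, dataset=spec,
                          model=ModelConfig(variant="hdcnet", depth=2, base_channels=16))
        record = train(cfg, phantom_pairs[:2])
        report = evaluate(record.model, spec, pairs=phantom_pairs[:2])
        assert report.acc >= 0.9

    def test_constant_half_model_gives_tie_auc(self, phantom_pairs):
        """Zeroing the head makes the output 0.5 everywhere; all-tied scores
        give AUC exactly 1/2."""
        model = build_model(ModelConfig(variant="hdcnet", **TINY), seed=0)
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = 0.0
        spec = DatasetSpec("phantom", (64, 64), (64, 64))
        report = evaluate(model, spec, pairs=phantom_pairs)
        assert report.auc == pytest.approx(0.5, abs=1e-12)

    def test_empty_test_partition_rejected(self):
        model = build_model(ModelConfig(variant="unet", **TINY))
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, DatasetSpec("phantom", (64, 64), (64, 64)), pairs=[])


class TestCrossTrain:
    def test_identical_specs_equal_plain_evaluation(self, phantom_pairs):
        spec = DatasetSpec("phantom", (64, 64), (64, 64))
        cfg = TrainConfig(epochs=2, seed=3, validation_fraction=0.0,
                          model=ModelConfig(variant="sd_unet", **TINY))
        report = cross_train(spec, spec, cfg, train_pairs=phantom_pairs[:2],
                             test_pairs=phantom_pairs[:2])
        cfg2 = TrainConfig(epochs=2, seed=3, validation_fraction=0.0, dataset=spec,
                           model=ModelConfig(variant="sd_unet", **TINY))
        record = train(cfg2, phantom_pairs[:2])
        direct = evaluate(record.model, spec, pairs=phantom_pairs[:2])
        assert report.as_dict() == pytest.approx(direct.as_dict(), nan_ok=True)

    def test_reports_all_metrics_across_resolutions(self, phantom_pairs):
        """The fully convolutional model trains at one resolution and
        evaluates at another."""
        from hdcnet.synthetic_fundus import PhantomSpec, generate

        train_spec = DatasetSpec("a", (64, 64), (64, 64))
        test_spec = DatasetSpec("b", (48, 48), (48, 48))
        test_pairs = [generate(PhantomSpec(size=(48, 48), seed=900 + i)) for i in range(2)]
        cfg = TrainConfig(epochs=2, seed=0, validation_fraction=0.0,
                          model=ModelConfig(variant="hdcnet", **TINY))
        report = cross_train(train_spec, test_spec, cfg, train_pairs=phantom_pairs[:2],
                             test_pairs=test_pairs)
        for v in report.as_dict().values():
            assert math.isfinite(v)
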