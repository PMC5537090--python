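"""Classifier harness: filter conversion, fine-tuning depth, training, prediction."""

import numpy as np
import pytest

from autobaa.augmentation import AugmentationConfig, _grid
from autobaa.classifier import (
    BoneAgeCNN,
    GRID_BASE_LRS,
    GRID_GAMMAS,
    TrainConfig,
    convert_filters_grayscale,
    grid_search,
    ingest,
    ingest_many,
    predict,
    set_finetune_depth,
    train,
)
from autobaa.errors import ConfigError, ShapeError
from autobaa.io import Radiograph, Sex


def toy_images(n_per_class=8, classes=(5, 9, 14), size=64, seed=0):
    """Square 'radiographs' whose bright-disk radius encodes the age class."""
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:size, 0:size]
    images = []
    for k, age in enumerate(classes):
        for _ in range(n_per_class):
            rad = size * (0.15 + 0.1 * k) + rng.normal(0, 0.3)
            img = ((rr - size / 2) ** 2 + (cc - size / 2) ** 2 <= rad**2) * 200.0
            img = np.clip(img + rng.normal(0, 4, (size, size)), 0, 255)
            images.append(
                Radiograph(
                    img.astype(np.uint8), sex=Sex.FEMALE, bone_age_label=age
                )
            )
    return images


class TestConvertFilters:
    def test_identical_channels(self):
        bank = np.ones((4, 3, 5, 5)) * 0.7
        out = convert_filters_grayscale(bank)
        assert out.shape == (4, 1, 5, 5)
        assert np.allclose(out, 0.7)

    def test_tap_mean(self):
        bank = np.zeros((1, 3, 1, 1))
        bank[0, :, 0, 0] = [0.3, 0.6, 0.9]
        assert np.isclose(convert_filters_grayscale(bank)[0, 0, 0, 0], 0.6)

    def test_bank_shape_and_oracle(self):
        rng = np.random.default_rng(0)
        bank = rng.normal(size=(64, 3, 7, 7))
        out = convert_filters_grayscale(bank)
        assert out.shape == (64, 1, 7, 7)
        assert np.allclose(out[:, 0], bank.mean(axis=1))

    def test_wrong_channel_count(self):
        with pytest.raises(ShapeError):
            convert_filters_grayscale(np.zeros((4, 4, 5, 5)))


class TestFinetuneDepth:
    def fitted(self):
        imgs = toy_images(n_per_class=4)
        X = ingest_many(imgs, 64)
        y = np.array([r.bone_age_label for r in imgs])
        m = BoneAgeCNN(input_size=64, epochs=1, batch_size=4, random_state=0,
                       val_fraction=0.25)
        with pytest.warns(UserWarning):
            m.finetune_depth = "fc"
            m.fit(X, y)
        return m, X, y

    def test_fc_only_trainable(self):
        m, _, _ = self.fitted()
        for name in ("conv1", "inception4", "inception5"):
            assert all(
                not p.trainable for p in m.net_.group_params(name) if not p.buffer
            )
        assert all(p.trainable for p in m.net_.group_params("fc"))

    def test_all_unfreezes_everything(self):
        m, _, _ = self.fitted()
        set_finetune_depth(m, "all")
        assert all(p.trainable for p in m.net_.params() if not p.buffer)

    def test_inception5_freezes_earlier_groups(self):
        m, _, _ = self.fitted()
        set_finetune_depth(m, "inception5")
        trainable = {
            name: all(p.trainable for p in m.net_.group_params(name) if not p.buffer)
            for name in m.net_.group_names
        }
        assert trainable == {
            "conv1": False, "inception4": False, "inception5": True, "fc": True
        }

    def test_unknown_depth(self):
        m, _, _ = self.fitted()
        with pytest.raises(ConfigError):
            set_finetune_depth(m, "conv9")

    def test_frozen_parameters_bit_identical_after_training(self):
        imgs = toy_images(n_per_class=6)
        X = ingest_many(imgs, 64)
        y = np.array([r.bone_age_label for r in imgs])
        m = BoneAgeCNN(input_size=64, epochs=3, batch_size=4,
                       finetune_depth="inception5", val_fraction=0.25,
                       random_state=3)
        with pytest.warns(UserWarning):
            m.fit(X, y)
        # rebuild the same random init and compare the frozen groups bit-for-bit
        init = m._build(np.random.default_rng(m.random_state + 9973 * 0)).state()
        final = m.net_.state()
        frozen = [p.name for g in ("conv1", "inception4")
                  for p in m.net_.group_params(g) if not p.buffer]
        trainable = [p.name for p in m.net_.group_params("fc")]
        assert all(np.array_equal(init[n], final[n]) for n in frozen)
        assert any(not np.array_equal(init[n], final[n]) for n in trainable)


class TestTraining:
    def test_learns_separable_toy_task(self):
        imgs = toy_images(n_per_class=10)
        cfg = TrainConfig(epochs=12, batch_size=8, base_lr=0.01, gamma=0.5,
                          input_size=64, val_fraction=0.2, seed=0)
        model, history = train(imgs, cfg)
        assert max(history["train_accuracy"]) >= 0.9
        assert model.validation_accuracy_ >= 0.8

    def test_seeded_determinism(self):
        imgs = toy_images(n_per_class=4)
        cfg = TrainConfig(epochs=3, batch_size=4, input_size=64,
                          val_fraction=0.25, seed=5)
        _, h1 = train(imgs, cfg)
        _, h2 = train(imgs, cfg)
        assert h1["val_accuracy"] == h2["val_accuracy"]
        assert h1["loss"] == h2["loss"]

    def test_batch_size_default_is_96(self):
        assert TrainConfig().batch_size == 96
        assert BoneAgeCNN().batch_size == 96

    def test_augmentation_not_inferior_at_matched_epochs(self):
        """Non-inferiority of on-line augmentation (2 sigma over 5 seeds).

        Uses a desk-scaled grid: the clinical-scale rotations are far larger
        than the geometric variation of a 36-image phantom cohort.
        """
        mild = AugmentationConfig(
            rotation_degrees=_grid(-3, 3, 1),
            width_scales=_grid(0.97, 1.0, 0.01),
            height_scales=_grid(0.97, 1.0, 0.01),
            shear_x_degrees=_grid(-2, 2, 1),
            shear_y_degrees=_grid(-2, 2, 1),
        )
        imgs = toy_images(n_per_class=8, seed=4)
        X = ingest_many(imgs, 64)
        y = np.array([r.bone_age_label for r in imgs])
        diffs = []
        for seed in range(5):
            accs = {}
            for aug in (None, mild):
                m = BoneAgeCNN(input_size=64, epochs=10, batch_size=8,
                               base_lr=0.01, gamma=0.5, augmentation=aug,
                               val_fraction=0.25, random_state=seed)
                m.fit(X, y)
                accs[aug is not None] = m.validation_accuracy_
            diffs.append(accs[True] - accs[False])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert diffs.mean() >= -2 * max(se, 1e-9)


class TestGridSearch:
    def test_nine_default_combinations(self):
        imgs = toy_images(n_per_class=4)
        fixed = TrainConfig(epochs=1, batch_size=4, input_size=64,
                            val_fraction=0.25, seed=0)
        best_cfg, best_model, results = grid_search(imgs, fixed=fixed)
        assert len(results) == len(GRID_BASE_LRS) * len(GRID_GAMMAS) == 9
        assert best_cfg.base_lr in GRID_BASE_LRS
        assert hasattr(best_model, "net_")

    def test_singleton_grid(self):
        imgs = toy_images(n_per_class=4)
        fixed = TrainConfig(epochs=1, batch_size=4, input_size=64,
                            val_fraction=0.25, seed=0)
        cfg, model, results = grid_search(imgs, lrs=[0.01], gammas=[0.5], fixed=fixed)
        assert len(results) == 1
        assert cfg.base_lr == 0.01 and cfg.gamma == 0.5

    def test_trained_beats_untrained_on_separable_task(self):
        imgs = toy_images(n_per_class=8)
        fixed = TrainConfig(batch_size=8, input_size=64, val_fraction=0.25, seed=0)
        accs = {}
        for epochs in (0, 10):
            cfg = fixed.replace(epochs=max(epochs, 1), base_lr=0.01 if epochs else 1e-12)
            model, history = train(imgs, cfg)
            accs[epochs] = history["best_val_accuracy"]
        assert accs[10] > accs[0]


class TestPrediction:
    def fitted(self):
        imgs = toy_images(n_per_class=6)
        cfg = TrainConfig(epochs=8, batch_size=8, base_lr=0.01, gamma=0.5,
                          input_size=64, val_fraction=0.25, seed=0)
        model, _ = train(imgs, cfg)
        return model, imgs

    def test_deterministic_and_14_classes(self):
        model, imgs = self.fitted()
        a = predict(model, imgs[0])
        b = predict(model, imgs[0])
        assert np.array_equal(a.probabilities, b.probabilities)
        assert len(a.probabilities) == 14
        assert abs(a.probabilities.sum() - 1.0) < 1e-6
        assert a.top1 == a.topk[0][0]
        probs = [p for _, p in a.topk]
        assert probs == sorted(probs, reverse=True)

    def test_non_square_rejected(self):
        model, _ = self.fitted()
        with pytest.raises(ShapeError):
            predict(model, Radiograph(np.zeros((64, 32), dtype=np.uint8)))

    def test_save_load_identical_predictions(self, tmp_path):
        model, imgs = self.fitted()
        model.save(tmp_path / "m.npz")
        back = BoneAgeCNN.load(tmp_path / "m.npz")
        x = ingest(imgs[0], 64)
        assert np.allclose(
            back.predict_proba(x[None]), model.predict_proba(x[None])
        )
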