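"""Metrics, sweep harness, occlusion maps and maturity staging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autobaa.errors import GeometryError, ShapeError, UndefinedIoUError
from autobaa.evaluation import (
    evaluate,
    iou,
    maturity_stage,
    miou,
    occlusion_map,
    patch_stride_sweep,
    positive_mass_fraction,
)
from autobaa.io import AGE_CLASSES, Radiograph, Sex


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate([5, 9, 14], [5, 9, 14])
        assert rep.top1_accuracy == 1.0 and rep.rmse == 0.0

    def test_hand_worked_example(self):
        rep = evaluate([7, 10], [5, 9])
        assert rep.top1_accuracy == 0.0
        assert rep.within1_accuracy == 0.5
        assert rep.within2_accuracy == 1.0
        assert np.isclose(rep.rmse, np.sqrt((4 + 1) / 2))

    def test_nested_accuracies_invariant(self):
        rng = np.random.default_rng(0)
        preds = rng.integers(5, 19, 200)
        truths = rng.integers(5, 19, 200)
        rep = evaluate(preds, truths)
        assert rep.top1_accuracy <= rep.within1_accuracy <= rep.within2_accuracy

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            evaluate([5, 6], [5])

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_matches_per_sample_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        preds = rng.integers(5, 19, n)
        truths = rng.integers(5, 19, n)
        rep = evaluate(preds, truths)
        # brute-force oracle: per-sample loop
        top1 = sum(int(p == t) for p, t in zip(preds, truths)) / n
        w1 = sum(int(abs(p - t) <= 1) for p, t in zip(preds, truths)) / n
        w2 = sum(int(abs(p - t) <= 2) for p, t in zip(preds, truths)) / n
        rmse = (sum((int(p) - int(t)) ** 2 for p, t in zip(preds, truths)) / n) ** 0.5
        assert rep.top1_accuracy == pytest.approx(top1)
        assert rep.within1_accuracy == pytest.approx(w1)
        assert rep.within2_accuracy == pytest.approx(w2)
        assert rep.rmse == pytest.approx(rmse)

    def test_map_perfect_ranking(self):
        truths = np.repeat(AGE_CLASSES, 3)
        probs = np.zeros((len(truths), 14))
        probs[np.arange(len(truths)), truths - 5] = 1.0
        rep = evaluate(truths, truths, probs)
        assert rep.map == pytest.approx(1.0)

    def test_map_shuffled_probabilities_near_prevalence(self):
        rng = np.random.default_rng(1)
        n = 700
        truths = rng.integers(5, 19, n)
        probs = rng.dirichlet(np.ones(14), size=n)
        rep = evaluate(truths, truths, probs)
        prevalence = np.mean([np.mean(truths == a) for a in AGE_CLASSES])
        assert abs(rep.map - prevalence) < 0.05  # Monte-Carlo bound


class TestMiou:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:8] = True
        assert miou([m, m], [m, m]) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool); a[:2] = True
        b = np.zeros((10, 10), bool); b[5:] = True
        assert miou([a], [b]) == 0.0

    def test_rectangle_overlap_one_third(self):
        a = np.zeros((200, 200), bool); a[0:100, 0:100] = True
        b = np.zeros((200, 200), bool); b[50:150, 0:100] = True
        assert iou(a, b) == pytest.approx(5000 / 15000)

    def test_both_empty_undefined(self):
        e = np.zeros((5, 5), bool)
        with pytest.raises(UndefinedIoUError):
            iou(e, e)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_matches_pixel_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((20, 20)) > 0.5
        b = rng.random((20, 20)) > 0.5
        inter = sum(
            1 for i in range(20) for j in range(20) if a[i, j] and b[i, j]
        )
        union = sum(
            1 for i in range(20) for j in range(20) if a[i, j] or b[i, j]
        )
        if union == 0:
            return
        assert iou(a, b) == pytest.approx(inter / union)


class TestSweepHarness:
    def test_singleton_grid_shape(self, detector_training_corpus):
        from autobaa.detection import sample_patches, train_patch_classifier

        corpus = detector_training_corpus[:2]

        def trainer(patch_size):
            data = sample_patches(corpus, 60, patch_size, seed=0)
            return train_patch_classifier(data, epochs=3, seed=0)

        table = patch_stride_sweep(corpus, trainer, strides=(16,), patch_sizes=(16,))
        assert list(table.columns) == ["patch_size", "stride", "miou"]
        assert len(table) == 1
        assert 0.0 <= table["miou"].iloc[0] <= 1.0

    def test_default_grids_would_give_28_cells(self):
        # enumeration only; training 28 detectors is the full-scale experiment
        strides, sizes = (2, 4, 8, 16), (16, 24, 32, 40, 48, 56, 64)
        assert len(strides) * len(sizes) == 28


class ToyRegionModel:
    """Score = mean intensity of one fixed 32x32 region (linear toy model)."""

    def __init__(self, r0=16, c0=16, size=64):
        self.r0, self.c0 = r0, c0
        self.input_size = size
        self.classes_ = np.asarray(AGE_CLASSES)

    def predict_proba(self, X):
        X = np.asarray(X)
        m = X[:, self.r0: self.r0 + 32, self.c0: self.c0 + 32].mean(axis=(1, 2))
        logits = np.zeros((len(X), 14))
        logits[:, 0] = 8 * m  # class 5 probability grows with region mean
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


class TestOcclusionMap:
    def image(self, size=64):
        px = np.full((size, size), 180, dtype=np.uint8)
        return Radiograph(px, sex=Sex.FEMALE, bone_age_label=5)

    def test_constant_model_zero_map(self):
        class Constant:
            input_size = 64
            classes_ = np.asarray(AGE_CLASSES)

            def predict_proba(self, X):
                out = np.zeros((len(X), 14))
                out[:, 3] = 1.0
                return out

        att = occlusion_map(Constant(), self.image(), 16, 8, target_class=8)
        assert np.allclose(att.values, 0.0)

    def test_toy_model_localizes_on_scored_region(self):
        model = ToyRegionModel()
        att = occlusion_map(model, self.image(), occluder_size=16,
                            occluder_stride=8, target_class=5)
        region = np.zeros((64, 64), bool)
        region[16:48, 16:48] = True
        # oracle: positions not intersecting the scored region change nothing
        for (i, j), v in np.ndenumerate(att.values):
            r, c = i * 8, j * 8
            overlaps = region[r: r + 16, c: c + 16].any()
            if not overlaps:
                assert abs(v) < 1e-9
        assert positive_mass_fraction(att, region) == pytest.approx(1.0)

    def test_full_size_occluder_single_position(self):
        att = occlusion_map(ToyRegionModel(), self.image(), occluder_size=64,
                            occluder_stride=8, target_class=5)
        assert att.values.shape == (1, 1)

    def test_oversized_occluder(self):
        with pytest.raises(GeometryError):
            occlusion_map(ToyRegionModel(), self.image(), occluder_size=128)

    def test_warns_on_misclassified_target(self):
        with pytest.warns(UserWarning):
            occlusion_map(ToyRegionModel(), self.image(), 32, 16, target_class=18)


class TestMaturityStage:
    @pytest.mark.parametrize(
        "sex,age,stage",
        [
            (Sex.FEMALE, 6, "prepuberty"),
            (Sex.FEMALE, 7, "early_mid_puberty"),  # lower-inclusive boundary
            (Sex.FEMALE, 13, "late_puberty"),
            (Sex.FEMALE, 15, "postpuberty"),
            (Sex.MALE, 8, "prepuberty"),
            (Sex.MALE, 9, "early_mid_puberty"),
            (Sex.MALE, 15, "late_puberty"),
            (Sex.MALE, 16.9, "late_puberty"),
            (Sex.MALE, 17, "postpuberty"),
        ],
    )
    def test_bins(self, sex, age, stage):
        assert maturity_stage(sex, age) == stage

    def test_negative_age(self):
        with pytest.raises(ValueError):
            maturity_stage(Sex.FEMALE, -1)
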