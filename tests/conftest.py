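"""Shared fixtures: phantom corpora and trained models (session-scoped).

The heavy fixtures (a patch detector trained on 500 patches per class, a
desk-scale bone-age classifier trained on 120 phantoms) are built once per
session and shared between the end-to-end tests.
"""

import pytest

from autobaa.classifier import TrainConfig, train
from autobaa.detection import sample_patches, train_patch_classifier
from autobaa.io import Sex
from autobaa.phantom import generate_cohort, normalize_with_truth
from autobaa.segmentation import vision_pipeline

#: six consecutive age classes used by the desk-scale classification checks
SIX_AGES = tuple(range(5, 11))


def preprocess_with_truth(radiograph, truth):
    """normalize + vision pipeline using the exact ground-truth hand mask."""
    nr, ngt = normalize_with_truth(radiograph, truth)
    img, shift = vision_pipeline(nr, ngt.hand_mask, return_shift=True)
    return img, shift, ngt


@pytest.fixture(scope="session")
def detector_training_corpus():
    """One normalized phantom per (sex, age class): 28 images with truth."""
    return [normalize_with_truth(r, t) for r, t in generate_cohort(1, seed=11)]


@pytest.fixture(scope="session")
def trained_detector(detector_training_corpus):
    """Patch detector trained on 500 phantom patches per class (32 px)."""
    data = sample_patches(detector_training_corpus, 500, patch_size=32, seed=11)
    return train_patch_classifier(data, epochs=30, seed=11)


@pytest.fixture(scope="session")
def phantom_classifier_bundle():
    """Desk-scale bone-age model over ages 5-10 plus a fresh held-out batch.

    Training: 20 female phantoms per class through the vision pipeline with
    ground-truth masks; 3 restarts selected on validation within-1 agreement.
    Held-out: 10 phantoms per class from an independent seed, returned as
    (preprocessed image, centering shift, normalized ground truth) triples.
    """
    train_images = []
    for r, gt in generate_cohort(
        20, sexes=[Sex.FEMALE], seed=101, age_classes=SIX_AGES
    ):
        img, _, _ = preprocess_with_truth(r, gt)
        train_images.append(img)
    cfg = TrainConfig(
        epochs=60, batch_size=8, base_lr=0.01, gamma=0.5, n_restarts=3, seed=101
    )
    model, history = train(train_images, cfg)

    held_out = []
    for r, gt in generate_cohort(
        10, sexes=[Sex.FEMALE], seed=1234, age_classes=SIX_AGES
    ):
        held_out.append(preprocess_with_truth(r, gt))
    return model, history, held_out


@pytest.fixture(scope="session")
def tiny_model_files(tmp_path_factory):
    """Small saved detector + classifier checkpoints for pipeline tests."""
    d = tmp_path_factory.mktemp("models")
    corpus = [
        normalize_with_truth(r, t)
        for r, t in generate_cohort(1, seed=3, age_classes=(5, 9, 14, 18))
    ]
    data = sample_patches(corpus, 150, patch_size=32, seed=3)
    detector = train_patch_classifier(data, epochs=10, seed=3)
    detector.save(d / "detector.npz")

    images = []
    for r, gt in generate_cohort(
        6, sexes=[Sex.FEMALE], seed=5, age_classes=(5, 9, 14)
    ):
        img, _, _ = preprocess_with_truth(r, gt)
        images.append(img)
    cfg = TrainConfig(
        epochs=15, batch_size=8, base_lr=0.01, gamma=0.5, val_fraction=0.2, seed=5
    )
    model, _ = train(images, cfg)
    model.save(d / "classifier.npz")
    return {"detector": d / "detector.npz", "classifier": d / "classifier.npz"}
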