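"""Bone-age classification: backbone, fine-tuning depth control, training.

The classifier assigns one of the 14 integer bone-age classes (5..18 years)
to a preprocessed radiograph, with separate models trained per sex.  The
backbone follows the inception pattern (stem convolution, inception blocks,
global average pooling, one fully connected output layer); the default
"small" width is sized for CPU training on phantom cohorts, and a wider
"full" variant is available behind the ``backbone`` flag.

Layer groups are ordered conv1 -> ... -> inception5 -> fc; the fine-tuning
depth names the earliest group whose weights are updated ("fc" trains the
head only, "all" updates everything starting from a pretrained
initialization, "scratch" updates everything from random initialization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .augmentation import AugmentationConfig, make_batch_augmenter
from .errors import (
    ConfigError,
    GridFailureError,
    ShapeError,
    TrainingFailureError,
)
from .io import AGE_CLASSES, MIN_BONE_AGE, Radiograph, Sex
from .persist import load_checkpoint, save_checkpoint

N_AGE_CLASSES = len(AGE_CLASSES)  # 14 classes, ages 5..18
INPUT_SIZE = 224


def convert_filters_grayscale(rgb_first_layer: np.ndarray) -> np.ndarray:
    """Collapse RGB first-layer filters to one channel by per-tap mean.

    ``rgb_first_layer`` has shape (n_filters, 3, k, k); the result has shape
    (n_filters, 1, k, k).  Used when adapting color-pretrained filters to
    grayscale radiographs.
    """
    bank = np.asarray(rgb_first_layer)
    if bank.ndim != 4 or bank.shape[1] != 3:
        raise ShapeError(
            f"expected (n_filters, 3, k, k) filter bank, got {bank.shape}"
        )
    return bank.mean(axis=1, keepdims=True)


def _small_backbone(rng, input_size: int = INPUT_SIZE) -> nn.Network:
    """Reduced-width inception-style network for desk-scale CPU training."""
    if input_size % 32 != 0:
        raise ConfigError(f"input size {input_size} must be a multiple of 32")
    conv1 = nn.Sequential(
        [
            nn.InputScale(),
            nn.Conv2D(1, 8, 7, stride=4, pad=3, rng=rng, name="conv1"),
            nn.ReLU(),
            nn.MaxPool2D(2),
        ]
    )
    inc4 = nn.Sequential(
        [
            nn.Inception(8, 4, 4, 8, 2, 4, 4, rng=rng, name="inception4"),
            nn.MaxPool2D(2),
        ]
    )
    inc5 = nn.Sequential(
        [nn.Inception(20, 6, 4, 10, 2, 4, 4, rng=rng, name="inception5")]
    )
    # coarse spatial pooling ahead of the linear head: the maturity signal
    # (physeal lucency) is small and location-bound, so a fully global average
    # would dilute it; the output layer starts at zero for calm early epochs
    final = input_size // 32
    head = nn.Dense(24 * final * final, N_AGE_CLASSES, rng=rng, name="fc")
    head.weight.value[...] = 0.0
    fc = nn.Sequential([nn.MaxPool2D(2), nn.Flatten(), head])
    return nn.Network(
        [("conv1", conv1), ("inception4", inc4), ("inception5", inc5), ("fc", fc)]
    )


def _full_backbone(rng) -> nn.Network:
    """Wider topology (same group structure) for larger runs."""
    conv1 = nn.Sequential(
        [
            nn.InputScale(),
            nn.Conv2D(1, 32, 7, stride=2, pad=3, rng=rng, name="conv1"),
            nn.ReLU(),
            nn.MaxPool2D(2),
            nn.Conv2D(32, 64, 3, pad=1, rng=rng, name="conv2"),
            nn.ReLU(),
            nn.MaxPool2D(2),
        ]
    )
    inc4 = nn.Sequential(
        [
            nn.Inception(64, 16, 16, 32, 8, 16, 16, rng=rng, name="inception4a"),
            nn.MaxPool2D(2),
            nn.Inception(80, 24, 16, 48, 8, 16, 16, rng=rng, name="inception4b"),
        ]
    )
    inc5 = nn.Sequential(
        [
            nn.MaxPool2D(2),
            nn.Inception(104, 32, 24, 64, 8, 24, 24, rng=rng, name="inception5"),
        ]
    )
    fc = nn.Sequential(
        [nn.GlobalAvgPool(), nn.Dense(144, N_AGE_CLASSES, rng=rng, name="fc")]
    )
    return nn.Network(
        [("conv1", conv1), ("inception4", inc4), ("inception5", inc5), ("fc", fc)]
    )


FINETUNE_DEPTHS = ("scratch", "all", "conv1", "inception4", "inception5", "fc")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one classification training run."""

    base_lr: float = 0.01
    gamma: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 0.005
    batch_size: int = 96
    epochs: int = 100
    finetune_depth: str = "scratch"
    augmentation: AugmentationConfig | None = None
    backbone: str = "small"
    input_size: int = INPUT_SIZE
    val_fraction: float = 0.15
    n_restarts: int = 1
    snapshot_metric: str = "within1"
    seed: int = 0

    def replace(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


#: hyperparameter grids of the 9-combination search
GRID_BASE_LRS = (0.001, 0.005, 0.01)
GRID_GAMMAS = (0.1, 0.5, 0.75)


class BoneAgeCNN(BaseEstimator, ClassifierMixin):
    """Inception-style bone-age classifier over the 14 age classes.

    A sklearn-style estimator: ``fit(X, y)`` takes ingested images
    ``(N, input_size, input_size)`` scaled to [0, 1] and integer year labels
    in [5, 18]; ``predict_proba`` returns a probability vector over the 14
    classes.  Training uses SGD (momentum, weight decay) with the learning
    rate multiplied by ``gamma`` at three evenly spaced epoch steps,
    optional on-line augmentation, and keeps the epoch snapshot with the
    best validation accuracy.
    """

    def __init__(
        self,
        backbone: str = "small",
        input_size: int = INPUT_SIZE,
        epochs: int = 100,
        base_lr: float = 0.01,
        gamma: float = 0.1,
        momentum: float = 0.9,
        weight_decay: float = 0.005,
        batch_size: int = 96,
        finetune_depth: str = "scratch",
        augmentation: AugmentationConfig | None = None,
        val_fraction: float = 0.15,
        n_restarts: int = 1,
        snapshot_metric: str = "within1",
        pretrained_state: dict | None = None,
        sex: Sex | None = None,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.input_size = input_size
        self.epochs = epochs
        self.base_lr = base_lr
        self.gamma = gamma
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.finetune_depth = finetune_depth
        self.augmentation = augmentation
        self.val_fraction = val_fraction
        self.n_restarts = n_restarts
        self.snapshot_metric = snapshot_metric
        self.pretrained_state = pretrained_state
        self.sex = sex
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build(self, rng) -> nn.Network:
        if self.backbone == "small":
            net = _small_backbone(rng, self.input_size)
        elif self.backbone == "full":
            net = _full_backbone(rng)
        else:
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.pretrained_state is not None:
            net.load_state(self.pretrained_state)
        return net

    def _apply_finetune_depth(self, net: nn.Network):
        depth = self.finetune_depth
        if depth in ("scratch", "all") or depth == net.group_names[0]:
            net.set_trainable_from(None)
            return
        if depth not in net.group_names:
            raise ConfigError(
                f"unknown fine-tune depth {depth!r}; expected one of "
                f"{('scratch', 'all') + tuple(net.group_names)}"
            )
        if self.pretrained_state is None:
            warnings.warn(
                f"fine-tune depth {depth!r} without pretrained parameters: "
                "frozen groups keep their random initialization",
                stacklevel=2,
            )
        net.set_trainable_from(depth)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ShapeError(
                f"expected (N, {self.input_size}, {self.input_size}) images, "
                f"got {X.shape}"
            )
        if y.min() < AGE_CLASSES[0] or y.max() > AGE_CLASSES[-1]:
            raise ValueError("labels must be integer years in [5, 18]")
        y_idx = y - MIN_BONE_AGE
        rng = np.random.default_rng(self.random_state)
        train_idx, val_idx = _stratified_holdout(y_idx, self.val_fraction, rng)
        augment = None
        if self.augmentation is not None:
            augment = make_batch_augmenter(self.augmentation, max_value=1.0)

        # several independently initialized runs; validation picks the model
        best = None
        for restart in range(max(1, self.n_restarts)):
            rng_r = np.random.default_rng(self.random_state + 9973 * restart)
            net = self._build(rng_r)
            self._apply_finetune_depth(net)
            history = nn.fit_network(
                net,
                X[train_idx][:, None],
                y_idx[train_idx],
                X[val_idx][:, None],
                y_idx[val_idx],
                epochs=self.epochs,
                base_lr=self.base_lr,
                gamma=self.gamma,
                momentum=self.momentum,
                weight_decay=self.weight_decay,
                batch_size=self.batch_size,
                rng=rng_r,
                augment=augment,
                val_metric=self.snapshot_metric,
            )
            if best is None or history["best_val_metric"] >= best[1]["best_val_metric"]:
                best = (net, history)
        self.net_, self.history_ = best
        self.classes_ = np.asarray(AGE_CLASSES)
        self.validation_accuracy_ = self.history_["best_val_accuracy"]
        train_pred = self.predict(X[train_idx])
        self.training_accuracy_ = float((train_pred == y[train_idx]).mean())
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != X.shape[2]:
            raise ShapeError(f"expected square inputs, got {X.shape}")
        if X.shape[1] != self.input_size:
            raise ShapeError(
                f"input size {X.shape[1]} does not match model "
                f"ingestion size {self.input_size}"
            )
        logits = nn.predict_logits(self.net_, X[:, None], batch_size=64)
        return nn.softmax(logits)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        params = self.get_params()
        params.pop("pretrained_state")
        params.pop("augmentation")
        sex = params.pop("sex")
        meta = {
            "topology": f"inception-{self.backbone}",
            "params": params,
            "sex": None if sex is None else Sex.coerce(sex).value,
        }
        save_checkpoint(path, meta, self.net_.state())

    @classmethod
    def load(cls, path) -> "BoneAgeCNN":
        meta, state = load_checkpoint(path)
        est = cls(**meta["params"])
        if meta.get("sex"):
            est.sex = Sex(meta["sex"])
        est.net_ = est._build(np.random.default_rng(0))
        est.net_.load_state(state)
        est.classes_ = np.asarray(AGE_CLASSES)
        return est


def _stratified_holdout(y_idx, val_fraction, rng):
    train, val = [], []
    for k in np.unique(y_idx):
        members = np.flatnonzero(y_idx == k)
        members = members[rng.permutation(len(members))]
        n_val = max(1, int(round(val_fraction * len(members))))
        val.append(members[:n_val])
        train.append(members[n_val:])
    return np.concatenate(train), np.concatenate(val)


def set_finetune_depth(model: BoneAgeCNN, depth: str) -> BoneAgeCNN:
    """Set which layer groups train: ``depth`` and all later groups.

    ``"all"`` trains everything from the (pretrained) initialization;
    ``"scratch"`` trains everything from random initialization.  Applies
    immediately to an already-built network.
    """
    if depth not in FINETUNE_DEPTHS:
        raise ConfigError(
            f"unknown fine-tune depth {depth!r}; expected one of {FINETUNE_DEPTHS}"
        )
    model.finetune_depth = depth
    if hasattr(model, "net_"):
        model._apply_finetune_depth(model.net_)
    return model


# ---------------------------------------------------------------------------
# Image ingestion
# ---------------------------------------------------------------------------

def ingest(image: Radiograph, input_size: int = INPUT_SIZE) -> np.ndarray:
    """Down-sample a preprocessed square radiograph for the network.

    Uses area-average (PIL BOX) resampling to ``input_size`` and scales
    intensities to [0, 1].  Non-square inputs are rejected: the classifier
    only accepts images that went through the preprocessing engine.
    """
    H, W = image.shape
    if H != W:
        raise ShapeError(f"classifier input must be square, got {(H, W)}")
    if (H, W) == (input_size, input_size):
        arr = image.pixels.astype(np.float32)
    else:
        pil = Image.fromarray(image.pixels.astype(np.float32), mode="F")
        arr = np.asarray(
            pil.resize((input_size, input_size), resample=Image.BOX),
            dtype=np.float32,
        )
    return arr / image.max_value


def ingest_many(images: Sequence[Radiograph], input_size: int = INPUT_SIZE):
    return np.stack([ingest(r, input_size) for r in images])


# ---------------------------------------------------------------------------
# Training harness
# ---------------------------------------------------------------------------

def train(
    images: Sequence[Radiograph],
    cfg: TrainConfig,
    sex: Sex | None = None,
) -> tuple[BoneAgeCNN, dict]:
    """Train one per-sex bone-age model on preprocessed labeled radiographs.

    Every image must carry ``bone_age_label``; if ``sex`` is given, only
    that cohort is used (models are trained separately per sex).  Returns
    the fitted model and its per-epoch history (loss, validation accuracy,
    learning rate).
    """
    if sex is not None:
        sex = Sex.coerce(sex)
        images = [r for r in images if r.sex == sex]
    labels = np.array([r.bone_age_label for r in images])
    if any(lbl is None for lbl in labels):
        raise ValueError("all training images need a bone_age_label")
    X = ingest_many(images, cfg.input_size)
    model = BoneAgeCNN(
        backbone=cfg.backbone,
        input_size=cfg.input_size,
        epochs=cfg.epochs,
        base_lr=cfg.base_lr,
        gamma=cfg.gamma,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
        batch_size=cfg.batch_size,
        finetune_depth=cfg.finetune_depth,
        augmentation=cfg.augmentation,
        val_fraction=cfg.val_fraction,
        n_restarts=cfg.n_restarts,
        snapshot_metric=cfg.snapshot_metric,
        sex=sex,
        random_state=cfg.seed,
    )
    model.fit(X, labels)
    return model, model.history_


def grid_search(
    images: Sequence[Radiograph],
    lrs: Sequence[float] = GRID_BASE_LRS,
    gammas: Sequence[float] = GRID_GAMMAS,
    fixed: TrainConfig = TrainConfig(),
    sex: Sex | None = None,
):
    """Train one model per (base_lr, gamma) pair; select by validation accuracy.

    Returns ``(best_config, best_model, results)`` where ``results`` is a
    DataFrame with one row per combination (NaN accuracy for runs whose loss
    diverged).  Raises :class:`GridFailureError` if every run fails.
    """
    if not len(lrs) or not len(gammas):
        raise ConfigError("grids must be non-empty")
    rows = []
    best = None
    for lr in lrs:
        for gamma in gammas:
            cfg = fixed.replace(base_lr=float(lr), gamma=float(gamma))
            try:
                model, history = train(images, cfg, sex=sex)
                acc = history["best_val_accuracy"]
            except TrainingFailureError:
                model, acc = None, np.nan
            rows.append({"base_lr": lr, "gamma": gamma, "val_accuracy": acc})
            if model is not None and (best is None or acc > best[2]):
                best = (cfg, model, acc)
    results = pd.DataFrame(rows)
    if best is None:
        raise GridFailureError("every grid-search run failed to converge")
    return best[0], best[1], results


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoneAgePrediction:
    """Probabilities over the 14 age classes plus ranked suggestions."""

    probabilities: np.ndarray  # (14,) summing to 1
    top1: int
    topk: tuple  # ((age, probability), ...) descending

    def __post_init__(self):
        if len(self.probabilities) != N_AGE_CLASSES:
            raise ShapeError("probabilities must cover the 14 age classes")


def predict(model: BoneAgeCNN, image: Radiograph, k: int = 5) -> BoneAgePrediction:
    """Deterministic bone-age prediction for one preprocessed radiograph."""
    x = ingest(image, model.input_size)
    probs = model.predict_proba(x[None])[0]
    order = np.argsort(-probs, kind="stable")
    topk = tuple(
        (int(model.classes_[i]), float(probs[i])) for i in order[: max(1, k)]
    )
    return BoneAgePrediction(
        probabilities=probs, top1=int(model.classes_[order[0]]), topk=topk
    )
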