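"""Patch sampling and the five-class LeNet-style detection CNN.

The detector is a patch classifier: given an S x S intensity patch from a
normalized radiograph it scores the five object classes (bone, tissue,
background, collimation, annotation).  A patch's ground-truth label is the
class of its center pixel.  Sliding the detector over a whole image (see
:mod:`autobaa.segmentation`) reconstructs a per-pixel label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .errors import InsufficientDataError, MissingClassError, ShapeError
from .labels import N_CLASSES, PixelClass
from .persist import load_checkpoint, save_checkpoint


@dataclass
class PatchDataset:
    """A class-balanced set of labeled S x S patches."""

    patches: np.ndarray  # (N, S, S) float32 in [0, 1]
    labels: np.ndarray  # (N,) integer PixelClass values
    patch_size: int
    seed: int

    def __post_init__(self):
        if self.patches.ndim != 3 or self.patches.shape[0] != len(self.labels):
            raise ShapeError("patches must be (N, S, S) with one label per patch")

    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def sample_patches(
    images,
    n_per_class: int,
    patch_size: int = 32,
    seed: int = 0,
) -> PatchDataset:
    """Sample a balanced patch dataset from (Radiograph, GroundTruth) pairs.

    Labels come from the ground-truth class of each patch's center pixel.
    Per class, candidate centers are drawn without replacement until
    exhausted, then with replacement.  Images must already be normalized
    (the detector is always applied to normalized images).
    """
    S = int(patch_size)
    half = S // 2
    rng = np.random.default_rng(seed)

    candidates: dict[int, list[np.ndarray]] = {int(k): [] for k in PixelClass}
    for img_idx, (radiograph, truth) in enumerate(images):
        cm = truth.class_map.labels
        H, W = cm.shape
        if H < S or W < S:
            continue
        interior = cm[half: H - S + half + 1, half: W - S + half + 1]
        for k in range(N_CLASSES):
            pos = np.argwhere(interior == k)
            if len(pos):
                pos = pos + half
                rows = np.column_stack(
                    [np.full(len(pos), img_idx, dtype=np.int64), pos]
                )
                candidates[k].append(rows)

    picks = {}
    for k in range(N_CLASSES):
        if not candidates[k]:
            raise MissingClassError(
                f"class {PixelClass(k).name} absent from every ground truth"
            )
        pool = np.concatenate(candidates[k], axis=0)
        if len(pool) >= n_per_class:
            sel = rng.choice(len(pool), size=n_per_class, replace=False)
        else:
            extra = rng.choice(len(pool), size=n_per_class - len(pool), replace=True)
            sel = np.concatenate([np.arange(len(pool)), extra])
        picks[k] = pool[sel]

    floats = [r.astype_float() for r, _ in images]
    patches = np.empty((n_per_class * N_CLASSES, S, S), dtype=np.float32)
    labels = np.empty(n_per_class * N_CLASSES, dtype=np.int64)
    i = 0
    for k in range(N_CLASSES):
        for img_idx, r, c in picks[k]:
            r0, c0 = r - half, c - half
            patches[i] = floats[img_idx][r0: r0 + S, c0: c0 + S]
            labels[i] = k
            i += 1
    return PatchDataset(patches, labels, patch_size=S, seed=seed)


def _lenet(patch_size: int, n_classes: int, rng) -> nn.Network:
    """LeNet-5-style topology: 2 conv+pool blocks, 2 fully connected layers."""
    c1_out = patch_size - 4
    c2_out = (c1_out // 2) - 4
    flat = 16 * (c2_out // 2) ** 2
    features = nn.Sequential(
        [
            nn.InputScale(),
            nn.Conv2D(1, 6, 5, rng=rng, name="conv1"),
            nn.ReLU(),
            nn.MaxPool2D(2),
            nn.Conv2D(6, 16, 5, rng=rng, name="conv2"),
            nn.ReLU(),
            nn.MaxPool2D(2),
        ]
    )
    head = nn.Sequential(
        [
            nn.Flatten(),
            nn.Dense(flat, 120, rng=rng, name="fc1"),
            nn.ReLU(),
            nn.Dense(120, n_classes, rng=rng, name="fc2"),
        ]
    )
    return nn.Network([("features", features), ("head", head)])


class PatchClassifierCNN(BaseEstimator, ClassifierMixin):
    """LeNet-5-style five-class patch classifier (sklearn-style estimator).

    Trains with SGD (momentum 0.9) for ``epochs`` epochs at ``base_lr``,
    dropping the learning rate tenfold at three evenly spaced steps; 25% of
    the patches per class are held out for validation and the
    best-by-validation-accuracy epoch snapshot is kept.

    Parameters follow the sklearn convention; fitted attributes end in an
    underscore (``net_``, ``classes_``, ``history_``,
    ``validation_accuracy_``).
    """

    def __init__(
        self,
        patch_size: int = 32,
        epochs: int = 100,
        base_lr: float = 0.01,
        gamma: float = 0.1,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        batch_size: int = 32,
        val_fraction: float = 0.25,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.epochs = epochs
        self.base_lr = base_lr
        self.gamma = gamma
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != self.patch_size or X.shape[2] != self.patch_size:
            raise ShapeError(
                f"expected (N, {self.patch_size}, {self.patch_size}) patches, "
                f"got {X.shape}"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        min_count = np.bincount(y_idx).min()
        if min_count < 10:
            raise InsufficientDataError(
                f"need >= 10 patches per class, smallest class has {min_count}"
            )
        rng = np.random.default_rng(self.random_state)

        train_idx, val_idx = self._holdout_split(y_idx, rng)
        net = _lenet(self.patch_size, len(self.classes_), rng)
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
            rng=rng,
        )
        self.net_ = net
        self.history_ = history
        self.validation_accuracy_ = history["best_val_accuracy"]
        self.patch_size_ = self.patch_size
        return self

    def _holdout_split(self, y_idx, rng):
        """Per-class holdout of ``val_fraction`` patches for validation."""
        train, val = [], []
        for k in range(y_idx.max() + 1):
            members = np.flatnonzero(y_idx == k)
            members = members[rng.permutation(len(members))]
            n_val = int(round(self.val_fraction * len(members)))
            val.append(members[:n_val])
            train.append(members[n_val:])
        return np.concatenate(train), np.concatenate(val)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.patch_size_, self.patch_size_):
            raise ShapeError(
                f"patch shape {X.shape[1:]} does not match model "
                f"size {self.patch_size_}"
            )
        logits = nn.predict_logits(self.net_, X[:, None], batch_size=1024)
        return nn.softmax(logits)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "topology": "lenet5-patch",
            "params": self.get_params(),
            "classes": np.asarray(self.classes_).tolist(),
        }
        save_checkpoint(path, meta, self.net_.state())

    @classmethod
    def load(cls, path) -> "PatchClassifierCNN":
        meta, state = load_checkpoint(path)
        est = cls(**meta["params"])
        est.classes_ = np.asarray(meta["classes"])
        est.net_ = _lenet(
            est.patch_size, len(est.classes_), np.random.default_rng(0)
        )
        est.net_.load_state(state)
        est.patch_size_ = est.patch_size
        return est


def train_patch_classifier(
    data: PatchDataset,
    epochs: int = 100,
    base_lr: float = 0.01,
    seed: int = 0,
    **kwargs,
) -> PatchClassifierCNN:
    """Fit a :class:`PatchClassifierCNN` on a sampled patch dataset."""
    model = PatchClassifierCNN(
        patch_size=data.patch_size,
        epochs=epochs,
        base_lr=base_lr,
        random_state=seed,
        **kwargs,
    )
    return model.fit(data.patches, data.labels)


def score_patch(model: PatchClassifierCNN, patch: np.ndarray) -> np.ndarray:
    """Score one patch; returns the 5-vector of class probabilities."""
    patch = np.asarray(patch, dtype=np.float32)
    if patch.shape != (model.patch_size_, model.patch_size_):
        raise ShapeError(
            f"patch shape {patch.shape} does not match model size "
            f"{model.patch_size_}"
        )
    return model.predict_proba(patch[None])[0]
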