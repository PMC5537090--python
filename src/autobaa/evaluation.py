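"""Metrics, the patch/stride sweep harness, occlusion attention maps and
maturity-stage binning.

Classification is scored with top-1 and within-k-year accuracy, RMSE (in
years) and macro-averaged one-vs-rest mean average precision; segmentation
with the mean Intersection-over-Union between predicted and ground-truth
hand masks.  Attention maps record how much the predicted probability of the
true class drops when a small occluder is slid across the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .errors import GeometryError, ShapeError, UndefinedIoUError
from .io import AGE_CLASSES, Radiograph, Sex


@dataclass(frozen=True)
class EvalReport:
    """Cohort-level classification metrics."""

    top1_accuracy: float
    within1_accuracy: float
    within2_accuracy: float
    rmse: float
    map: float | None
    n: int
    cohort: str = ""

    def __post_init__(self):
        if not (
            self.top1_accuracy <= self.within1_accuracy <= self.within2_accuracy <= 1.0
        ):
            raise ValueError("within-k accuracies must be nested")


def evaluate(
    predictions,
    truths,
    probabilities=None,
    cohort: str = "",
) -> EvalReport:
    """Score integer year predictions against reported bone ages.

    ``probabilities`` (one 14-vector per case, ordered by age class 5..18)
    enables the mAP term: the unweighted mean over classes present in the
    truth of one-vs-rest average precision, ranking cases by that class's
    probability.
    """
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 1:
        raise ShapeError("predictions and truths must be equal-length 1-D")
    err = pred - truth
    top1 = float((err == 0).mean())
    within1 = float((np.abs(err) <= 1).mean())
    within2 = float((np.abs(err) <= 2).mean())
    rmse = float(np.sqrt(np.mean(err**2)))

    mean_ap = None
    if probabilities is not None:
        probs = np.asarray(probabilities, dtype=float)
        if probs.shape != (len(pred), len(AGE_CLASSES)):
            raise ShapeError(
                f"probabilities must be (n, {len(AGE_CLASSES)}), got {probs.shape}"
            )
        aps = []
        for j, age in enumerate(AGE_CLASSES):
            positives = truth == age
            if positives.any():
                aps.append(average_precision_score(positives, probs[:, j]))
        mean_ap = float(np.mean(aps))
    return EvalReport(top1, within1, within2, rmse, mean_ap, n=len(pred), cohort=cohort)


def iou(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over Union of two binary masks."""
    a = np.asarray(predicted, dtype=bool)
    b = np.asarray(truth, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedIoUError("both masks empty; IoU undefined")
    return float(np.logical_and(a, b).sum() / union)


def miou(predicted_masks, truth_masks) -> float:
    """Arithmetic mean of per-pair IoU values."""
    predicted_masks = list(predicted_masks)
    truth_masks = list(truth_masks)
    if len(predicted_masks) != len(truth_masks) or not predicted_masks:
        raise ShapeError("need equal, non-zero numbers of predicted/truth masks")
    return float(
        np.mean([iou(p, t) for p, t in zip(predicted_masks, truth_masks)])
    )


def patch_stride_sweep(
    corpus,
    detector_trainer,
    strides=(2, 4, 8, 16),
    patch_sizes=(16, 24, 32, 40, 48, 56, 64),
    segment=None,
) -> pd.DataFrame:
    """mIoU of the preprocessing engine over a stride x patch-size grid.

    ``detector_trainer(patch_size)`` must return a trained patch classifier
    for that size; ``segment(image, model, patch_size, stride)`` must return
    a predicted binary hand mask (defaults to the package's label-map ->
    largest-component pipeline).  ``corpus`` is the evaluation set of
    normalized (Radiograph, GroundTruth) pairs.  Returns a DataFrame with
    one row per combination.
    """
    if segment is None:
        from .errors import EmptySegmentationError
        from .pipeline import segment_hand

        def segment(image, model, patch_size, stride):
            try:
                return segment_hand(image, model, patch_size, stride).mask
            except EmptySegmentationError:
                # a failed segmentation scores IoU 0 instead of aborting the sweep
                return np.zeros(image.shape, dtype=bool)

    rows = []
    for patch_size in patch_sizes:
        model = detector_trainer(patch_size)
        for stride in strides:
            preds, truths = [], []
            for image, truth in corpus:
                preds.append(segment(image, model, patch_size, stride))
                truths.append(truth.hand_mask.mask)
            rows.append(
                {
                    "patch_size": patch_size,
                    "stride": stride,
                    "miou": miou(preds, truths),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Occlusion attention maps
# ---------------------------------------------------------------------------

@dataclass
class AttentionMap:
    """Probability change of the target class per occluder position.

    ``values[i, j]`` is ``p_target(original) - p_target(occluded)`` for the
    occluder whose top-left corner sits at
    ``(i * occluder_stride, j * occluder_stride)``; positive values mark
    regions whose occlusion hurts the target class.
    """

    values: np.ndarray
    occluder_size: int
    occluder_stride: int
    target_class: int

    def positions(self):
        nr, nc = self.values.shape
        s = self.occluder_stride
        return [(i * s, j * s) for i in range(nr) for j in range(nc)]


def occlusion_map(
    model,
    image: Radiograph,
    occluder_size: int = 16,
    occluder_stride: int = 8,
    target_class: int | None = None,
    batch_size: int = 64,
) -> AttentionMap:
    """Slide a zero-filled occluder over the image and record probability drops.

    ``target_class`` defaults to the image's reported bone age when present,
    else the model's own prediction.  A warning (not an error) is raised if
    the unoccluded image is not classified as the target class, since
    attention maps are conventionally read on correctly classified inputs.
    """
    from .classifier import ingest

    x = ingest(image, model.input_size)
    S = x.shape[0]
    if occluder_size > S:
        raise GeometryError(
            f"occluder {occluder_size} larger than ingested image {S}"
        )
    p0 = model.predict_proba(x[None])[0]
    classes = list(model.classes_)
    if target_class is None:
        target_class = (
            image.bone_age_label
            if image.bone_age_label is not None
            else int(model.classes_[int(np.argmax(p0))])
        )
    tgt = classes.index(int(target_class))
    if int(np.argmax(p0)) != tgt:
        warnings.warn(
            "image is not classified as the target class; attention map may "
            "be unreliable",
            stacklevel=2,
        )

    starts = list(range(0, S - occluder_size + 1, occluder_stride))
    occluded = np.empty((len(starts) * len(starts), S, S), dtype=np.float32)
    idx = 0
    for r in starts:
        for c in starts:
            occ = x.copy()
            occ[r: r + occluder_size, c: c + occluder_size] = 0.0
            occluded[idx] = occ
            idx += 1
    probs = np.concatenate(
        [
            model.predict_proba(occluded[i: i + batch_size])
            for i in range(0, len(occluded), batch_size)
        ]
    )
    values = (p0[tgt] - probs[:, tgt]).reshape(len(starts), len(starts))
    return AttentionMap(
        values=values,
        occluder_size=occluder_size,
        occluder_stride=occluder_stride,
        target_class=int(target_class),
    )


def positive_mass_fraction(att: AttentionMap, region_mask: np.ndarray) -> float:
    """Fraction of positive attention mass at positions overlapping a region.

    ``region_mask`` is a boolean grid in the same (ingested) image frame; an
    occluder position counts as overlapping if its window intersects the
    region.  Returns 0 when there is no positive mass.
    """
    pos = np.clip(att.values, 0.0, None)
    total = pos.sum()
    if total == 0:
        return 0.0
    s, k = att.occluder_stride, att.occluder_size
    overlap_mass = 0.0
    for (i, j), v in np.ndenumerate(pos):
        if v <= 0:
            continue
        r, c = i * s, j * s
        if region_mask[r: r + k, c: c + k].any():
            overlap_mass += v
    return float(overlap_mass / total)


def save_attention_overlay(
    att: AttentionMap, image: Radiograph, path, input_size: int = 224
) -> None:
    """Write a heat overlay PNG of an attention map on its source image."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from .classifier import ingest

    x = ingest(image, input_size)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(x, cmap="gray")
    extent = (0, x.shape[1], x.shape[0], 0)
    ax.imshow(att.values, cmap="jet", alpha=0.45, extent=extent)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Maturity stages
# ---------------------------------------------------------------------------

MATURITY_STAGES = ("prepuberty", "early_mid_puberty", "late_puberty", "postpuberty")

#: lower-inclusive stage boundaries (years) per sex
_STAGE_BOUNDS = {
    Sex.FEMALE: (7.0, 13.0, 15.0),
    Sex.MALE: (9.0, 14.0, 17.0),
}


def maturity_stage(sex, bone_age_years: float) -> str:
    """Skeletal maturity stage for a bone age, by sex.

    Female bins: [0,7), [7,13), [13,15), [15,inf); male bins: [0,9),
    [9,14), [14,17), [17,inf).  Intervals are lower-inclusive.
    """
    if bone_age_years < 0:
        raise ValueError(f"bone age must be non-negative, got {bone_age_years}")
    b1, b2, b3 = _STAGE_BOUNDS[Sex.coerce(sex)]
    if bone_age_years < b1:
        return MATURITY_STAGES[0]
    if bone_age_years < b2:
        return MATURITY_STAGES[1]
    if bone_age_years < b3:
        return MATURITY_STAGES[2]
    return MATURITY_STAGES[3]
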