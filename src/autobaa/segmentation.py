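"""Label-map reconstruction, hand-mask generation and the vision pipeline.

The detection CNN scores S x S patches; sliding it over a normalized
radiograph yields per-pixel class scores.  Each pixel's label is the argmax
of the mean score vector of every patch covering it.  Bone+tissue pixels
form the hand region; the largest connected component, hole-filled, is the
segmentation mask handed to the vision pipeline (artifact removal,
centering, contrast equalization, denoising, sharpening).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage import exposure, filters, measure

from .errors import EmptySegmentationError, GeometryError, ShapeError
from .io import Radiograph
from .labels import HAND_CLASSES, N_CLASSES


@dataclass
class RegionLabelMap:
    """Per-pixel assignment over the five radiograph object classes."""

    labels: np.ndarray  # 2-D uint8 grid of PixelClass values

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ShapeError("label map must be 2-D")
        if self.labels.max(initial=0) >= N_CLASSES:
            raise ShapeError("label map contains values outside the 5 classes")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class HandMask:
    """Binary hand/non-hand mask (one solid 4-connected component)."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ShapeError("hand mask must be 2-D")

    @property
    def shape(self):
        return self.mask.shape


def build_label_map(
    image: Radiograph,
    model,
    patch_size: int = 32,
    stride: int = 4,
    batch_size: int = 4096,
) -> RegionLabelMap:
    """Reconstruct a per-pixel label map by sliding-window patch scoring.

    Every grid-aligned patch (top-left at multiples of ``stride``, fully
    inside the image) is scored by ``model.predict_proba``; each pixel
    accumulates the mean score vector of the patches covering it and is
    labeled with the argmax class (ties broken by class order).  Pixels not
    covered by any patch (possible near borders when ``stride > 1``) inherit
    the nearest covered pixel's label.
    """
    H, W = image.shape
    P = int(patch_size)
    if P > H or P > W:
        raise GeometryError(f"patch size {P} exceeds image shape {(H, W)}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > P:
        warnings.warn(
            f"stride {stride} > patch size {P}: some pixels are never scored",
            stacklevel=2,
        )

    x = image.astype_float()
    windows = sliding_window_view(x, (P, P))[::stride, ::stride]  # (nr, nc, P, P)
    nr, nc = windows.shape[:2]
    rows = (np.arange(nr) * stride).astype(np.intp)
    cols = (np.arange(nc) * stride).astype(np.intp)

    scores = np.empty((nr, nc, N_CLASSES), dtype=np.float64)
    rows_per_chunk = max(1, batch_size // max(nc, 1))
    for r0 in range(0, nr, rows_per_chunk):
        r1 = min(nr, r0 + rows_per_chunk)
        chunk = np.ascontiguousarray(windows[r0:r1]).reshape(-1, P, P)
        scores[r0:r1] = np.asarray(model.predict_proba(chunk)).reshape(
            r1 - r0, nc, N_CLASSES
        )

    # Integral-image accumulation: each patch adds its score vector over its
    # P x P footprint; 2-D cumulative sums then give per-pixel score sums.
    rr = np.repeat(rows, nc)
    cc = np.tile(cols, nr)
    flat_scores = scores.reshape(-1, N_CLASSES)
    diff = np.zeros((H + 1, W + 1, N_CLASSES), dtype=np.float64)
    np.add.at(diff, (rr, cc), flat_scores)
    np.add.at(diff, (rr, cc + P), -flat_scores)
    np.add.at(diff, (rr + P, cc), -flat_scores)
    np.add.at(diff, (rr + P, cc + P), flat_scores)
    score_sum = diff.cumsum(axis=0).cumsum(axis=1)[:H, :W]

    cdiff = np.zeros((H + 1, W + 1), dtype=np.int64)
    np.add.at(cdiff, (rr, cc), 1)
    np.add.at(cdiff, (rr, cc + P), -1)
    np.add.at(cdiff, (rr + P, cc), -1)
    np.add.at(cdiff, (rr + P, cc + P), 1)
    count = cdiff.cumsum(axis=0).cumsum(axis=1)[:H, :W]

    labels = np.argmax(score_sum, axis=2).astype(np.uint8)
    uncovered = count == 0
    if uncovered.any():
        _, (ir, ic) = ndimage.distance_transform_edt(uncovered, return_indices=True)
        labels[uncovered] = labels[ir[uncovered], ic[uncovered]]
    return RegionLabelMap(labels)


def labelmap_to_hand(label_map: RegionLabelMap) -> np.ndarray:
    """Binary grid: True where the label is bone or tissue."""
    return np.isin(label_map.labels, np.array(HAND_CLASSES, dtype=np.uint8))


def generate_mask(hand: np.ndarray) -> HandMask:
    """Clean hand mask: largest 4-connected component with holes filled.

    Ties on component area are broken by the smallest top-left coordinate in
    row-major order.  Raises :class:`EmptySegmentationError` if no pixel is
    set.
    """
    hand = np.asarray(hand, dtype=bool)
    if not hand.any():
        raise EmptySegmentationError("no hand pixels to build a mask from")
    labeled = measure.label(hand, connectivity=1)
    areas = np.bincount(labeled.ravel())
    areas[0] = 0
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area)
    if len(candidates) > 1:
        flat = labeled.ravel()
        candidates = sorted(candidates, key=lambda lab: int(np.argmax(flat == lab)))
    keep = labeled == candidates[0]
    filled = ndimage.binary_fill_holes(keep)
    return HandMask(filled)


def _integer_shift(arr: np.ndarray, dr: int, dc: int, fill=0) -> np.ndarray:
    """Translate a 2-D array by whole pixels, filling vacated cells."""
    out = np.full_like(arr, fill)
    H, W = arr.shape
    src_r = slice(max(0, -dr), min(H, H - dr))
    src_c = slice(max(0, -dc), min(W, W - dc))
    dst_r = slice(max(0, dr), min(H, H + dr))
    dst_c = slice(max(0, dc), min(W, W + dc))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def vision_pipeline(
    image: Radiograph,
    mask: HandMask,
    return_shift: bool = False,
):
    """Standardize a masked radiograph for classification.

    Steps, in order: zero everything outside the mask; translate so the mask
    bounding-box center coincides with the image center; histogram-equalize
    using the in-mask intensity distribution only; 3x3 median denoising;
    unsharp-mask sharpening (radius 1, amount 1).  All enhancement is
    confined to the (translated) mask; the output shape equals the input
    shape.  With ``return_shift`` the applied (row, col) translation is also
    returned.
    """
    if image.shape != mask.shape:
        raise ShapeError(f"image {image.shape} and mask {mask.shape} differ")
    m = mask.mask
    if not m.any():
        raise EmptySegmentationError("empty mask passed to the vision pipeline")

    px = image.pixels.copy()
    px[~m] = 0

    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    bc_r = (rows[0] + rows[-1]) / 2.0
    bc_c = (cols[0] + cols[-1]) / 2.0
    H, W = m.shape
    dr = int(round((H - 1) / 2.0 - bc_r))
    dc = int(round((W - 1) / 2.0 - bc_c))
    px = _integer_shift(px, dr, dc)
    m = _integer_shift(m, dr, dc, fill=False)

    maxv = image.max_value
    eq = exposure.equalize_hist(px, nbins=min(maxv + 1, 4096), mask=m)
    eq = np.where(m, eq, 0.0)

    den = ndimage.median_filter(eq, size=3)
    den = np.where(m, den, 0.0)

    sharp = filters.unsharp_mask(den, radius=1.0, amount=1.0)
    sharp = np.where(m, np.clip(sharp, 0.0, 1.0), 0.0)

    out = np.rint(sharp * maxv).astype(image.pixels.dtype)
    result = image.with_pixels(out)
    if return_shift:
        return result, (dr, dc)
    return result
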