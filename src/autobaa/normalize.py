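"""Grayscale-base and size normalization (first stage of preprocessing).

Radiographs arrive with either bright bones on a dark background or the
inverse, and at wildly varying sizes.  Both nuisances are removed before the
detection CNN sees the image: the grayscale base is standardized to
black-background by a four-corner brightness test, and the image is rescaled
and zero-padded to 512 x 512.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .errors import GeometryError
from .io import Radiograph

TARGET_SIZE = 512
_CORNER = 10


def corner_mean(r: Radiograph) -> float:
    """Mean of the four 10x10 corner-patch means."""
    px = r.pixels
    H, W = px.shape
    if H < _CORNER or W < _CORNER:
        raise GeometryError(f"image {px.shape} smaller than {_CORNER}x{_CORNER}")
    c = _CORNER
    corners = (px[:c, :c], px[:c, -c:], px[-c:, :c], px[-c:, -c:])
    return float(np.mean([p.mean() for p in corners]))


def normalize_grayscale_base(r: Radiograph) -> Radiograph:
    """Standardize to a black background.

    If the average of the four 10x10 corner-patch means exceeds half the
    representable maximum (128 at 8 bits), the image is inverted
    (``v -> maxval - v``); otherwise it is returned unchanged.  The output
    always passes the same test, so the filter is idempotent.
    """
    threshold = (1 << r.bit_depth) / 2.0
    if corner_mean(r) > threshold:
        return r.with_pixels(r.max_value - r.pixels)
    return r


def normalize_size(r: Radiograph, target: int = TARGET_SIZE) -> Radiograph:
    """Rescale to ``target x target`` with aspect preserved and zero padding.

    The content is scaled (bilinear) so its larger dimension equals
    ``target``; the remaining rows/columns are zero-padded symmetrically
    (extra pixel on the trailing side when the pad is odd).  Run after
    :func:`normalize_grayscale_base` so the padding matches the background.
    """
    px = r.pixels
    H, W = px.shape
    if (H, W) == (target, target):
        return r
    scale = target / max(H, W)
    new_h = min(target, max(1, int(round(H * scale))))
    new_w = min(target, max(1, int(round(W * scale))))
    content = resize(
        px.astype(np.float64),
        (new_h, new_w),
        order=1,
        mode="constant",
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    out = np.zeros((target, target), dtype=px.dtype)
    r0 = (target - new_h) // 2
    c0 = (target - new_w) // 2
    out[r0: r0 + new_h, c0: c0 + new_w] = np.clip(
        np.rint(content), 0, r.max_value
    ).astype(px.dtype)
    return r.with_pixels(out)


def normalize(r: Radiograph, target: int = TARGET_SIZE) -> Radiograph:
    """Grayscale-base normalization followed by size normalization."""
    return normalize_size(normalize_grayscale_base(r), target)
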