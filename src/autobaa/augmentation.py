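"""Real-time data augmentation: affine + photometric grids with switches.

Each training presentation draws one value per enabled transform from a
finite grid — rotation angle, anisotropic width/height scale, x/y shear,
and a pixel transform ``v -> alpha * v + beta`` — and each transform is
independently switched on with a configurable probability.  The default
grids give 61 rotations, 150 resize combinations, 121 shear combinations
and 100 pixel transforms: 110,715,000 distinct synthetic images per input.

Geometric transforms compose into a single affine map about the image
center (no translation component: inputs are centered by preprocessing, and
horizontal flips are never used because hand radiographs are left hands by
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import Radiograph


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameter grids and per-transform enable switches."""

    rotation_degrees: tuple = field(default_factory=lambda: _grid(-30, 30, 1))
    width_scales: tuple = field(default_factory=lambda: _grid(0.85, 0.99, 0.01))
    height_scales: tuple = field(default_factory=lambda: _grid(0.90, 0.99, 0.01))
    shear_x_degrees: tuple = field(default_factory=lambda: _grid(-5, 5, 1))
    shear_y_degrees: tuple = field(default_factory=lambda: _grid(-5, 5, 1))
    alphas: tuple = field(default_factory=lambda: _grid(0.90, 0.99, 0.01))
    betas: tuple = field(default_factory=lambda: tuple(range(1, 11)))
    rotation_enabled: bool = True
    resize_enabled: bool = True
    shear_enabled: bool = True
    pixel_enabled: bool = True
    #: probability that each enabled transform is applied per draw
    switch_prob: float = 0.5
    seed: int = 0

    def disabled(self, **flags) -> "AugmentationConfig":
        return replace(self, **flags)


def default_config() -> AugmentationConfig:
    """The study's default augmentation grids (Table-of-methods defaults)."""
    return AugmentationConfig()


def cardinality(config: AugmentationConfig) -> int:
    """Number of distinct synthetic images one input can map to.

    The product of enabled transforms' grid sizes; resize counts
    ``|width| * |height|``, shear ``|x| * |y|`` and the pixel transform
    ``|alpha| * |beta|``.  Disabled transforms contribute a factor of 1.
    """
    total = 1
    if config.rotation_enabled:
        total *= len(config.rotation_degrees)
    if config.resize_enabled:
        total *= len(config.width_scales) * len(config.height_scales)
    if config.shear_enabled:
        total *= len(config.shear_x_degrees) * len(config.shear_y_degrees)
    if config.pixel_enabled:
        total *= len(config.alphas) * len(config.betas)
    return total


@dataclass(frozen=True)
class AugmentationDraw:
    """One concrete transform: a value per grid (identity when switched off)."""

    rotation_deg: float = 0.0
    width_scale: float = 1.0
    height_scale: float = 1.0
    shear_x_deg: float = 0.0
    shear_y_deg: float = 0.0
    alpha: float = 1.0
    beta: int = 0

    @property
    def is_identity(self) -> bool:
        return self == AugmentationDraw()


def draw(config: AugmentationConfig, rng: np.random.Generator) -> AugmentationDraw:
    """Draw one augmentation uniformly and independently from each grid.

    Each enabled transform fires with probability ``config.switch_prob``;
    otherwise it contributes its identity value (0 deg rotation, scale 1,
    alpha 1 / beta 0).  Deterministic given the generator state.
    """
    def pick(values):
        return values[int(rng.integers(len(values)))]

    d = {}
    if config.rotation_enabled and rng.random() < config.switch_prob:
        d["rotation_deg"] = float(pick(config.rotation_degrees))
    if config.resize_enabled and rng.random() < config.switch_prob:
        d["width_scale"] = float(pick(config.width_scales))
        d["height_scale"] = float(pick(config.height_scales))
    if config.shear_enabled and rng.random() < config.switch_prob:
        d["shear_x_deg"] = float(pick(config.shear_x_degrees))
        d["shear_y_deg"] = float(pick(config.shear_y_degrees))
    if config.pixel_enabled and rng.random() < config.switch_prob:
        d["alpha"] = float(pick(config.alphas))
        d["beta"] = int(pick(config.betas))
    return AugmentationDraw(**d)


def _affine_matrix(d: AugmentationDraw) -> np.ndarray:
    """Forward affine map (row, col) -> (row, col): rotation . shear . scale."""
    th = np.deg2rad(d.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array(
        [
            [1.0, np.tan(np.deg2rad(d.shear_y_deg))],
            [np.tan(np.deg2rad(d.shear_x_deg)), 1.0],
        ]
    )
    scale = np.diag([d.height_scale, d.width_scale])
    return rot @ shear @ scale


def apply_array(
    x: np.ndarray, d: AugmentationDraw, max_value: float
) -> np.ndarray:
    """Apply a draw to a raw 2-D intensity array (float in, float out).

    The affine part is composed into one transform about the image center
    with bilinear resampling and zero fill; the pixel transform then clips
    ``alpha * v + beta`` to ``[0, max_value]``.  The beta grid is defined in
    8-bit intensity counts, so it is rescaled by ``max_value / 255`` for
    other dynamic ranges (e.g. [0, 1]-normalized training batches).
    """
    out = x.astype(np.float64, copy=True)
    m = _affine_matrix(d)
    if not np.allclose(m, np.eye(2)):
        center = (np.asarray(x.shape) - 1) / 2.0
        inv = np.linalg.inv(m)
        offset = center - inv @ center
        out = ndimage.affine_transform(
            out, inv, offset=offset, order=1, mode="constant", cval=0.0
        )
    if d.alpha != 1.0 or d.beta != 0:
        out = d.alpha * out + d.beta * (max_value / 255.0)
    return np.clip(out, 0.0, max_value)


def apply(image: Radiograph, d: AugmentationDraw) -> Radiograph:
    """Apply a draw to a (preprocessed, black-background) radiograph."""
    out = apply_array(image.pixels, d, image.max_value)
    return image.with_pixels(np.rint(out).astype(image.pixels.dtype))


def make_batch_augmenter(config: AugmentationConfig, max_value: float = 1.0):
    """Streaming augmenter for training: ``f(batch, rng) -> batch``.

    Draws a fresh transform per image per call; images are never
    materialized to disk (augmentation happens while the previous batch
    trains, mirroring on-the-fly augmentation).
    """

    def augment(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty_like(batch)
        for i in range(len(batch)):
            img = batch[i, 0] if batch.ndim == 4 else batch[i]
            res = apply_array(img, draw(config, rng), max_value)
            if batch.ndim == 4:
                out[i, 0] = res
            else:
                out[i] = res
        return out

    return augment
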