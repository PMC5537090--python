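"""Synthetic hand-radiograph phantoms with exact per-pixel ground truth.

Real bone-age cohorts cannot be redistributed, so the package ships a
generator of hand-like phantoms that reproduces the nuisance variability a
preprocessing engine must survive -- variable image sizes, inverted
grayscale bases, collimation borders, annotation markers, additive noise --
plus one learnable maturity signal: a growth-plate gap in every finger bone
whose width shrinks linearly with the bone-age class and closes at 18 years,
a cartoon of physeal closure.

Geometry is proportional to the image size, so the gap width measured after
512-normalization depends only on the age class, not on the raw image size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError
from .io import AGE_CLASSES, MAX_BONE_AGE, MIN_BONE_AGE, Radiograph, Sex
from .labels import PixelClass
from .segmentation import HandMask, RegionLabelMap, generate_mask

#: base intensity per class, as a fraction of the dynamic range
CLASS_INTENSITY = {
    PixelClass.BACKGROUND: 0.02,
    PixelClass.COLLIMATION: 0.25,
    PixelClass.TISSUE: 0.45,
    PixelClass.BONE: 0.85,
    PixelClass.ANNOTATION: 0.95,
}

#: additive Gaussian noise, sigma as a fraction of the dynamic range
NOISE_SIGMA = 0.02

#: rendered intensity of the growth-plate gap: physes are radiolucent, darker
#: than the surrounding soft tissue (the gap pixels remain tissue-class)
GAP_INTENSITY = 0.28

#: growth-plate gap in pixels at 512-pixel image height
def gap_width_512(bone_age_class: int) -> int:
    """Growth-plate gap width (px at 512 scale); linear in age, 0 at 18."""
    return max(0, round(12 * (MAX_BONE_AGE - bone_age_class) / 13))


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs give identical output."""

    height: int
    width: int
    sex: Sex
    bone_age_class: int
    white_background: bool = False
    collimation: bool = False
    marker: bool = False
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if not MIN_BONE_AGE <= self.bone_age_class <= MAX_BONE_AGE:
            raise ValueError(f"bone_age_class {self.bone_age_class} outside [5, 18]")


@dataclass
class GroundTruth:
    """Exact labels for a phantom: class map, hand mask and gap locations."""

    class_map: RegionLabelMap
    hand_mask: HandMask
    #: half-open (r0, r1, c0, c1) box of each finger's growth-plate gap
    gap_boxes: list = field(default_factory=list)


# relative finger layout: (x center / W, top / H, half width factor)
_FINGERS = (
    (0.20, 0.32, 1.00),
    (0.35, 0.20, 1.00),
    (0.50, 0.13, 1.05),
    (0.65, 0.20, 1.00),
    (0.80, 0.31, 0.95),
)


def generate_phantom(spec: PhantomSpec) -> tuple[Radiograph, GroundTruth]:
    """Render one phantom radiograph and its exact ground truth.

    The class map is emitted from the geometry before noise and grayscale
    inversion are applied, so it is exact by construction.
    """
    H, W = int(spec.height), int(spec.width)
    if H < 64 or W < 64:
        raise GeometryError(f"phantom needs at least 64x64 pixels, got {(H, W)}")
    rng = np.random.default_rng(spec.seed)
    cm = np.full((H, W), PixelClass.BACKGROUND, dtype=np.uint8)

    size_factor = 1.04 if spec.sex == Sex.MALE else 1.0
    rr, cc = np.mgrid[0:H, 0:W]

    # palm ellipse
    pr = H * (0.64 + 0.01 * rng.uniform(-1, 1))
    pc = W * (0.50 + 0.01 * rng.uniform(-1, 1))
    pa = H * 0.165 * size_factor
    pb = W * 0.300 * size_factor
    palm = ((rr - pr) / pa) ** 2 + ((cc - pc) / pb) ** 2 <= 1.0
    cm[palm] = PixelClass.TISSUE

    # wrist / forearm
    wr0 = int(H * 0.74)
    wc0, wc1 = int(W * 0.34), int(W * 0.66)
    cm[wr0:H, wc0:wc1] = PixelClass.TISSUE

    gap_px = round(gap_width_512(spec.bone_age_class) * H / 512.0)
    gap_boxes: list[tuple[int, int, int, int]] = []
    gap_region = np.zeros((H, W), dtype=bool)

    finger_half = W * 0.036 * size_factor
    for fx, ftop, wfac in _FINGERS:
        xc = W * (fx + 0.004 * rng.uniform(-1, 1))
        top = H * (ftop + 0.008 * rng.uniform(-1, 1))
        half = finger_half * wfac
        c0, c1 = int(round(xc - half)), int(round(xc + half))
        r0 = int(round(top))
        r1 = int(round(H * 0.70))
        cm[r0:r1, max(0, c0):c1] = PixelClass.TISSUE
        # rounded fingertip
        tip = (rr - r0) ** 2 + (cc - xc) ** 2 <= half**2
        cm[tip] = PixelClass.TISSUE

        # bone bar inside the finger, interrupted by the growth-plate gap
        bhalf = 0.70 * half
        bc0, bc1 = int(round(xc - bhalf)), int(round(xc + bhalf))
        br0 = r0 + max(1, int(round(H * 0.02)))
        br1 = int(round(H * 0.68))
        cm[br0:br1, max(0, bc0):bc1] = PixelClass.BONE
        # one physis per phalanx/metacarpal segment, all closing together
        for seg in (0.10, 0.22, 0.34):
            g0 = r0 + int(round(H * seg))
            if gap_px > 0:
                cm[g0: g0 + gap_px, max(0, bc0):bc1] = PixelClass.TISSUE
                gap_region[g0: g0 + gap_px, max(0, bc0):bc1] = True
            gap_boxes.append((g0, g0 + max(gap_px, 1), max(0, bc0), bc1))

    # carpal bones and distal radius/ulna
    for (yr, yc, rad) in ((0.66, 0.43, 0.030), (0.68, 0.57, 0.030)):
        blob = (rr - H * yr) ** 2 + (cc - W * yc) ** 2 <= (H * rad) ** 2
        cm[blob] = PixelClass.BONE
    for xfrac in (0.42, 0.58):
        bc = int(W * xfrac)
        bw = max(2, int(W * 0.025))
        cm[int(H * 0.78): H, bc - bw: bc + bw] = PixelClass.BONE
        # distal radial/ulnar physis -- the last growth plate to close
        g0 = int(H * 0.80)
        if gap_px > 0:
            cm[g0: g0 + gap_px, bc - bw: bc + bw] = PixelClass.TISSUE
            gap_region[g0: g0 + gap_px, bc - bw: bc + bw] = True
        gap_boxes.append((g0, g0 + max(gap_px, 1), bc - bw, bc + bw))

    if spec.collimation:
        t = max(2, int(round(0.04 * min(H, W))))
        border = np.zeros((H, W), dtype=bool)
        border[:t, :] = border[-t:, :] = True
        border[:, :t] = border[:, -t:] = True
        border &= cm == PixelClass.BACKGROUND
        cm[border] = PixelClass.COLLIMATION

    if spec.marker:
        mr0 = int(H * 0.08)
        mc0 = int(W * 0.875)
        mr1 = min(H, mr0 + max(3, int(H * 0.05)))
        mc1 = min(W, mc0 + max(3, int(W * 0.035)))
        cm[mr0:mr1, mc0:mc1] = PixelClass.ANNOTATION

    # ground truth before noise / inversion
    class_map = RegionLabelMap(cm)
    hand_mask = generate_mask(
        np.isin(cm, (int(PixelClass.BONE), int(PixelClass.TISSUE)))
    )
    truth = GroundTruth(class_map=class_map, hand_mask=hand_mask, gap_boxes=gap_boxes)

    maxv = (1 << spec.bit_depth) - 1
    base = np.empty((H, W), dtype=np.float64)
    for klass, level in CLASS_INTENSITY.items():
        base[cm == klass] = level * maxv
    base[gap_region] = GAP_INTENSITY * maxv  # radiolucent physis
    img = base + rng.normal(0.0, NOISE_SIGMA * maxv, size=(H, W))
    img = np.clip(np.rint(img), 0, maxv)
    if spec.white_background:
        img = maxv - img
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    radiograph = Radiograph(
        img.astype(dtype),
        bit_depth=spec.bit_depth,
        sex=spec.sex,
        bone_age_label=spec.bone_age_class,
        source_id=f"phantom-{spec.sex.value}-{spec.bone_age_class:02d}-s{spec.seed}",
    )
    return radiograph, truth


def normalize_with_truth(
    radiograph: Radiograph, truth: GroundTruth, target: int = 512
) -> tuple[Radiograph, GroundTruth]:
    """Normalize a phantom and transform its ground truth identically.

    The class map is rescaled with nearest-neighbor interpolation and padded
    with the background class; the hand mask is rebuilt from the transformed
    class map, and gap boxes are mapped through the same scale and offset.
    """
    from skimage.transform import resize as _resize

    from .normalize import normalize

    normalized = normalize(radiograph, target)
    cm = truth.class_map.labels
    H, W = cm.shape
    scale = target / max(H, W)
    new_h = min(target, max(1, int(round(H * scale))))
    new_w = min(target, max(1, int(round(W * scale))))
    cm_small = _resize(
        cm, (new_h, new_w), order=0, preserve_range=True, anti_aliasing=False
    ).astype(np.uint8)
    out = np.full((target, target), int(PixelClass.BACKGROUND), dtype=np.uint8)
    r0 = (target - new_h) // 2
    c0 = (target - new_w) // 2
    out[r0: r0 + new_h, c0: c0 + new_w] = cm_small
    class_map = RegionLabelMap(out)
    hand_mask = generate_mask(
        np.isin(out, (int(PixelClass.BONE), int(PixelClass.TISSUE)))
    )
    boxes = [
        (
            int(round(b0 * scale)) + r0,
            max(int(round(b0 * scale)) + r0 + 1, int(round(b1 * scale)) + r0),
            int(round(b2 * scale)) + c0,
            max(int(round(b2 * scale)) + c0 + 1, int(round(b3 * scale)) + c0),
        )
        for (b0, b1, b2, b3) in truth.gap_boxes
    ]
    return normalized, GroundTruth(class_map, hand_mask, boxes)


def generate_cohort(
    n_per_class: int,
    sexes: Iterable[Sex | str] = (Sex.FEMALE, Sex.MALE),
    seed: int = 0,
    size_range: tuple[int, int] = (320, 640),
    age_classes: Sequence[int] = AGE_CLASSES,
    bit_depth_choices: Sequence[int] = (8, 8, 8, 16),
) -> list[tuple[Radiograph, GroundTruth]]:
    """Generate ``n_per_class`` phantoms per (sex, age class) pair.

    Image heights are drawn uniformly from ``size_range`` at a fixed 3:4
    width:height aspect; grayscale base, collimation and markers are
    randomized with probability 0.5 each.  Fully deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    sexes = [Sex.coerce(s) for s in sexes]
    rng = np.random.default_rng(seed)
    cohort: list[tuple[Radiograph, GroundTruth]] = []
    for sex in sexes:
        for age in age_classes:
            for _ in range(n_per_class):
                h = int(rng.integers(size_range[0], size_range[1] + 1))
                w = int(round(0.75 * h))
                spec = PhantomSpec(
                    height=h,
                    width=w,
                    sex=sex,
                    bone_age_class=int(age),
                    white_background=bool(rng.random() < 0.5),
                    collimation=bool(rng.random() < 0.5),
                    marker=bool(rng.random() < 0.5),
                    bit_depth=int(rng.choice(np.asarray(bit_depth_choices))),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                cohort.append(generate_phantom(spec))
    return cohort
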