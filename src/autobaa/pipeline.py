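"""End-to-end preprocessing: normalization, segmentation, vision pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .io import Radiograph
from .normalize import TARGET_SIZE, normalize
from .segmentation import (
    HandMask,
    RegionLabelMap,
    build_label_map,
    generate_mask,
    labelmap_to_hand,
    vision_pipeline,
)


@dataclass
class PreprocessResult:
    """All intermediate artifacts of one preprocessing run."""

    normalized: Radiograph
    label_map: RegionLabelMap
    hand_mask: HandMask
    preprocessed: Radiograph
    shift: tuple[int, int]


def segment_hand(
    normalized: Radiograph, detector, patch_size: int = 32, stride: int = 4
) -> HandMask:
    """Label-map reconstruction + largest-component mask for one image."""
    label_map = build_label_map(normalized, detector, patch_size, stride)
    return generate_mask(labelmap_to_hand(label_map))


def preprocess(
    image: Radiograph,
    detector,
    patch_size: int = 32,
    stride: int = 4,
    target: int = TARGET_SIZE,
) -> PreprocessResult:
    """Run the full preprocessing engine on a raw radiograph.

    normalize (grayscale base + size) -> sliding-window label map ->
    bone+tissue -> largest-component hole-filled mask -> vision pipeline
    (mask, center, equalize, denoise, sharpen).
    """
    normalized = normalize(image, target)
    label_map = build_label_map(normalized, detector, patch_size, stride)
    mask = generate_mask(labelmap_to_hand(label_map))
    final, shift = vision_pipeline(normalized, mask, return_shift=True)
    return PreprocessResult(
        normalized=normalized,
        label_map=label_map,
        hand_mask=mask,
        preprocessed=final,
        shift=shift,
    )
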