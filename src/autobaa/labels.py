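"""The five pixel classes visible on a hand radiograph.

Integer values double as the deterministic argmax tie-break order used when
reconstructing label maps from patch scores.
"""

from enum import IntEnum


class PixelClass(IntEnum):
    BONE = 0
    TISSUE = 1
    BACKGROUND = 2
    COLLIMATION = 3
    ANNOTATION = 4


N_CLASSES = len(PixelClass)

#: Classes that belong to the hand/wrist region.
HAND_CLASSES = (PixelClass.BONE, PixelClass.TISSUE)
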