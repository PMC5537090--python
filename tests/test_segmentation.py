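"""Label-map reconstruction, mask generation and the vision pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from autobaa.errors import EmptySegmentationError, GeometryError, ShapeError
from autobaa.io import Radiograph
from autobaa.labels import N_CLASSES, PixelClass
from autobaa.segmentation import (
    HandMask,
    RegionLabelMap,
    build_label_map,
    generate_mask,
    labelmap_to_hand,
    vision_pipeline,
)


class CountingConstantModel:
    """Scores every patch with a fixed vector; records how many it saw."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)
        self.n_seen = 0

    def predict_proba(self, patches):
        self.n_seen += len(patches)
        return np.tile(self.scores, (len(patches), 1))


class OracleModel:
    """One-hot score of the center pixel's ground-truth class."""

    def __init__(self, class_map):
        self.cm = class_map
        self.positions = iter(())

    def bind(self, patch_size, stride, shape):
        H, W = shape
        P = patch_size
        rows = range(0, H - P + 1, stride)
        cols = range(0, W - P + 1, stride)
        self._centers = [
            (r + P // 2, c + P // 2) for r in rows for c in cols
        ]
        self._cursor = 0
        return self

    def predict_proba(self, patches):
        out = np.zeros((len(patches), N_CLASSES))
        for i in range(len(patches)):
            r, c = self._centers[self._cursor]
            out[i, self.cm[r, c]] = 1.0
            self._cursor += 1
        return out


def radiograph(shape=(512, 512), fill=50):
    return Radiograph(np.full(shape, fill, dtype=np.uint8))


class TestBuildLabelMap:
    def test_patch_position_count_512_32_4(self):
        model = CountingConstantModel([1, 0, 0, 0, 0])
        build_label_map(radiograph(), model, patch_size=32, stride=4)
        assert model.n_seen == ((512 - 32) // 4 + 1) ** 2 == 14641

    def test_constant_model_uniform_map(self):
        model = CountingConstantModel([0.1, 0.1, 0.6, 0.1, 0.1])
        lm = build_label_map(radiograph((96, 96)), model, 16, 8)
        assert (lm.labels == PixelClass.BACKGROUND).all()
        assert lm.shape == (96, 96)

    def test_oracle_model_recovers_truth_in_uniform_interior(self):
        # ground truth: a bone rectangle on background
        cm = np.full((96, 96), int(PixelClass.BACKGROUND), dtype=np.uint8)
        cm[24:72, 30:66] = int(PixelClass.BONE)
        P = 8
        model = OracleModel(cm).bind(P, 1, (96, 96))
        lm = build_label_map(radiograph((96, 96)), model, patch_size=P, stride=1)
        # oracle of vote averaging: exact where the P//2 neighborhood is uniform
        uniform_bone = ndimage.binary_erosion(
            cm == PixelClass.BONE, iterations=P // 2
        )
        uniform_bg = ndimage.binary_erosion(
            cm == PixelClass.BACKGROUND, iterations=P // 2, border_value=1
        )
        assert (lm.labels[uniform_bone] == PixelClass.BONE).all()
        assert (lm.labels[uniform_bg] == PixelClass.BACKGROUND).all()

    def test_uncovered_border_inherits_nearest_label(self):
        model = CountingConstantModel([0, 1, 0, 0, 0])
        lm = build_label_map(radiograph((70, 70)), model, patch_size=32, stride=16)
        # positions cover only up to 32+16=48.. rest inherits
        assert (lm.labels == PixelClass.TISSUE).all()

    def test_patch_larger_than_image(self):
        with pytest.raises(GeometryError):
            build_label_map(radiograph((30, 30)), CountingConstantModel([1, 0, 0, 0, 0]), 32, 4)

    def test_stride_above_patch_warns(self):
        with pytest.warns(UserWarning):
            build_label_map(
                radiograph((96, 96)), CountingConstantModel([1, 0, 0, 0, 0]),
                patch_size=16, stride=24,
            )


class TestLabelmapToHand:
    def test_bone_tissue_only(self):
        labels = np.array(
            [[PixelClass.BONE, PixelClass.TISSUE, PixelClass.BACKGROUND],
             [PixelClass.COLLIMATION, PixelClass.ANNOTATION, PixelClass.BONE]],
            dtype=np.uint8,
        )
        hand = labelmap_to_hand(RegionLabelMap(labels))
        assert hand.tolist() == [[True, True, False], [False, False, True]]

    def test_partition_complement(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, N_CLASSES, (40, 40)).astype(np.uint8)
        hand = labelmap_to_hand(RegionLabelMap(labels))
        assert hand.sum() + (~hand).sum() == labels.size


class TestGenerateMask:
    def test_largest_component_kept(self):
        grid = np.zeros((100, 100), dtype=bool)
        grid[10:60, 10:60] = True  # area 2500
        grid[80:90, 80:84] = True  # area 40, distant
        mask = generate_mask(grid).mask
        assert mask[20, 20] and not mask[85, 81]

    def test_hole_filled(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[5:25, 5:25] = True
        grid[12:15, 12:15] = False  # 3x3 interior hole
        mask = generate_mask(grid).mask
        assert mask.sum() == 20 * 20  # hole refilled: area increases by 9

    def test_idempotent(self):
        grid = np.zeros((50, 50), dtype=bool)
        grid[5:30, 5:30] = True
        once = generate_mask(grid).mask
        twice = generate_mask(once).mask
        assert np.array_equal(once, twice)

    def test_empty_input(self):
        with pytest.raises(EmptySegmentationError):
            generate_mask(np.zeros((10, 10), dtype=bool))

    def test_single_component_result(self):
        rng = np.random.default_rng(3)
        grid = rng.random((60, 60)) > 0.7
        mask = generate_mask(grid).mask
        from skimage.measure import label

        assert label(mask, connectivity=1).max() == 1


class TestVisionPipeline:
    def test_constant_full_mask_invariance(self):
        img = radiograph((64, 64), fill=77)
        mask = HandMask(np.ones((64, 64), dtype=bool))
        out = vision_pipeline(img, mask)
        assert out.shape == (64, 64)
        assert out.pixels.std() == 0  # constant stays constant

    def test_centering_bounding_box(self):
        px = np.zeros((512, 512), dtype=np.uint8)
        px[10:110, 20:80] = 200  # off-center 100x60 blob
        img = Radiograph(px)
        mask = HandMask(px > 0)
        out, (dr, dc) = vision_pipeline(img, mask, return_shift=True)
        rows = np.flatnonzero(out.pixels.any(axis=1))
        cols = np.flatnonzero(out.pixels.any(axis=0))
        assert abs((rows[0] + rows[-1]) / 2 - 255.5) <= 0.5
        assert abs((cols[0] + cols[-1]) / 2 - 255.5) <= 0.5

    def test_artifacts_outside_mask_removed(self):
        px = np.zeros((128, 128), dtype=np.uint8)
        px[40:80, 40:80] = 120
        px[5, 5] = 255  # artifact outside the mask
        mask = np.zeros((128, 128), dtype=bool)
        mask[40:80, 40:80] = True
        out = vision_pipeline(Radiograph(px), HandMask(mask))
        assert out.pixels[5, 5] == 0

    def test_zero_outside_translated_mask(self):
        px = np.zeros((128, 128), dtype=np.uint8)
        px[10:50, 10:50] = 99
        mask = px > 0
        out, (dr, dc) = vision_pipeline(
            Radiograph(px), HandMask(mask), return_shift=True
        )
        shifted_mask = np.zeros_like(mask)
        shifted_mask[10 + dr: 50 + dr, 10 + dc: 50 + dc] = True
        assert (out.pixels[~shifted_mask] == 0).all()

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            vision_pipeline(radiograph((30, 30)), HandMask(np.ones((20, 20), bool)))

    def test_empty_mask(self):
        with pytest.raises(EmptySegmentationError):
            vision_pipeline(
                radiograph((30, 30)), HandMask(np.zeros((30, 30), bool))
            )
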