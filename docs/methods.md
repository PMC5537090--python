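# Methods

This note documents the models, parameters and design choices behind
`autobaa`, and what the synthetic phantoms do and do not establish about
performance on clinical radiographs.

## Pipeline model

A bone-age assessment is produced in five stages, each a pure function of
its inputs so the end-to-end system is deterministic.

**Grayscale-base normalization.** The mean of the four 10×10 corner-patch
means is compared with half the representable maximum (128 at 8 bits, 32768
at 16 bits); if it exceeds the threshold the image is inverted. The four
corners are averaged (rather than voted) so that one corner occupied by a
marker cannot flip the decision. The filter is idempotent: its output always
passes the same test.

**Size normalization.** The content is scaled (bilinear, anti-aliased when
downscaling) so its larger dimension equals 512, then zero-padded
symmetrically to 512×512 (odd padding puts the extra pixel on the trailing
side). Padding with zeros is correct only after black-background
normalization, which is why the stages are ordered.

**Detection.** The five-class patch classifier is a LeNet-5-style network —
conv(1→6, 5×5) → pool → conv(6→16, 5×5) → pool → fc(→120) → fc(→5) — on
patches scaled to [0, 1] and internally remapped to [−1, 1]. A patch's label
is the ground-truth class of its center pixel. Training: SGD with momentum
0.9, base learning rate 0.01 dropped tenfold at ¼, ½ and ¾ of the epoch
budget, 25% of patches per class held out, best-validation-epoch snapshot
kept (the most-trained snapshot among ties). The default patch size is 32
and stride 4, the optimum of the patch/stride sweep harness
(`autobaa.evaluation.patch_stride_sweep`).

**Label-map reconstruction.** Every grid-aligned patch position is scored;
a pixel's score is the mean vector over all covering patches, its label the
argmax (ties broken in the fixed class order bone < tissue < background <
collimation < annotation). The accumulation uses an integral-image trick
(four corner updates per patch + two cumulative sums), so reconstruction is
O(positions + pixels) rather than O(positions × patch area). Pixels covered
by no patch (borders when stride > 1) inherit the nearest covered pixel's
label via a Euclidean distance transform.

**Mask generation and vision pipeline.** Bone+tissue pixels form the hand
proposal; the largest 4-connected component is kept (area ties broken by the
earliest pixel in row-major order) and interior holes are filled. The vision
pipeline zeroes everything outside the mask, translates the mask's
bounding-box center to the image center (integer shift; bounding box rather
than centroid so the shift is robust to intensity distribution), equalizes
the histogram computed over in-mask pixels only (so the zeroed background
cannot dominate), applies a 3×3 median filter and an unsharp mask (radius 1,
amount 1), all confined to the mask. Order follows the stage list:
equalize → denoise → sharpen.

**Classification.** Images are ingested at 224×224 by area-average (BOX)
downsampling and scaled to [0, 1]. The desk-scale backbone is a
reduced-width inception-style network: stem conv(7×7, stride 4, 8 ch) +
pool, inception block (20 ch) + pool, inception block (24 ch), then a 2×2
max-pool, flatten (24·7·7) and a linear layer over the 14 classes. A fully
global average pool — the head the full-scale topology uses — was evaluated
and rejected for the desk-scale network: the discriminative feature
(physeal lucency) occupies ≈0.1% of the image, and global averaging diluted
it below what SGD could recover at these sample sizes; the coarse 7×7
spatial pooling preserves the location-bound signal. The output layer is
zero-initialized so early epochs are calm. A wider `backbone="full"` variant
(global-average-pool head) exists behind a flag for larger runs.

Training uses SGD (momentum 0.9, weight decay 0.005, batch 96 by default)
with the learning rate multiplied by `gamma` at three evenly spaced steps;
base learning rates {0.001, 0.005, 0.01} × gamma {0.1, 0.5, 0.75} form the
default 3×3 grid search. Because small-sample CNN training can land in poor
optima, `BoneAgeCNN` supports `n_restarts`: several independently
initialized runs with the validation set selecting the final model — the
protocol's stated role for the validation data. Snapshot and restart
selection default to within-1-year validation agreement, the ordinal metric
that matters clinically; plain top-1 accuracy is available via
`snapshot_metric="accuracy"`. Models are trained separately per sex.

**Fine-tuning depth.** Layer groups are ordered conv1 → inception4 →
inception5 → fc. A depth names the earliest trainable group; earlier groups
are frozen (their parameters are bit-identical before and after training).
`all` trains everything from the provided initialization, `scratch` from
random initialization. No pretrained weights ship with the package; when a
fine-tune depth is requested without `pretrained_state`, freezing is honored
but a warning notes that frozen groups keep random weights.
`convert_filters_grayscale` collapses 3-channel first-layer filters to one
channel by per-tap mean for adapting color-pretrained banks.

**Augmentation.** Each training presentation draws one value per enabled
transform from finite grids — rotation −30°…30° step 1° (61), width scale
0.85…0.99 and height scale 0.90…0.99 step 0.01 (150 combinations), x/y
shear −5°…5° step 1° (121), pixel transform `v → αv + β` with α 0.90…0.99
step 0.01 and integer β 1…10 (100) — giving 61·150·121·100 = 110,715,000
distinct synthetic images per input. β is defined on the 8-bit intensity
scale and is rescaled by `max_value/255` for other dynamic ranges. Each
transform fires independently with probability 0.5 per draw (configurable);
the geometric part composes into a single affine map about the image center
(bilinear, zero fill). Horizontal flips and translations are never applied:
bone-age radiographs are left hands by convention and preprocessing already
centers the content. Augmentation is a streaming per-batch transform, never
materialized to disk.

**Occlusion attention maps.** A zero-filled square occluder slides across
the ingested image; the map records `p_target(original) −
p_target(occluded)` per position. Defaults: occluder 16, stride 8 at the
224-px scale (configurable). Maps are conventionally read on correctly
classified inputs; the function warns (not errors) otherwise.

**Maturity stages.** Lower-inclusive bins: female [0,7) / [7,13) / [13,15) /
[15,∞), male [0,9) / [9,14) / [14,17) / [17,∞) years for prepuberty,
early-mid puberty, late puberty, postpuberty. The male late-puberty bin is
extended through age 16 so the bins partition the axis.

**Reports.** `run_pipeline` chains read → normalize → label map → mask →
vision pipeline → classify → report, tagging errors with the failing stage.
Reports carry 3–5 ranked age suggestions (requests outside that range are
clamped with a warning), the maturity stage, package version and model-file
hashes. No atlas images are bundled; suggestions are age classes with
probabilities.

## Report parsing and splits

Bone-age statements are located after the keywords "bone age" or
"skeletal"; ranges ("13 to 14", "13–14") resolve to the arithmetic mean
computed in months, and the result is floored to whole years, so "13 to 14
years" gives 13. "Skeletally mature" and any value above 18 map to 18;
values below 5 raise an out-of-cohort error (the 0–4-year bracket is
excluded); reports with conflicting statements are rejected rather than
guessed. Dataset splits are simple random 70/15/15 (validation and test each
`round(0.15·N)`), deterministic given the seed; an optional stratified mode
exists for tiny synthetic sets.

## The phantom generator

`generate_phantom` renders a hand-like scene: a palm ellipse, five finger
capsules of soft-tissue intensity containing brighter bone bars, two carpal
blobs, and a wrist with radius/ulna bars. Each finger bone carries three
growth plates (one per phalanx/metacarpal segment) and each wrist bone one
(the distal radial/ulnar physis); a physis is a radiolucent band — darker
(0.28 of the dynamic range) than tissue (0.45) as on real radiographs —
whose class remains *tissue* in the ground truth. The gap width is
`g(age) = max(0, round(12·(18−age)/13))` pixels at 512-pixel height — linear,
monotone, closed at 18 — and all geometry is proportional to the image size,
so the gap measured after 512-normalization depends only on the age class.
Rendered intensities (fraction of dynamic range): background 0.02,
collimation 0.25, tissue 0.45, bone 0.85, annotation 0.95, plus clipped
Gaussian noise with σ = 2% of the range. Options: white-background
inversion, a collimation frame, a bright annotation block, 8- or 16-bit
depth. `generate_cohort` randomizes size (heights 320–640 at fixed 3:4
aspect), grayscale base, collimation, markers and bit depth per image;
identical specs give identical phantoms.

What the phantoms emulate: grayscale-base and size variability, the five
pixel classes, balanced patch sampling, an age signal that is local,
monotone and sex-agnostic. What they do not: real anatomy (carpal
ossification sequences, epiphyseal shape change), projection and exposure
physics, pathology, label noise from report parsing, or inter-rater
ambiguity. Passing the phantom suites therefore establishes that the
*pipeline machinery* is correct and that the classifier can learn a
localized maturity cue from images — not that clinical accuracy figures
would be reproduced on hospital data.

## Problem sizes used by the test suite

Chosen to exercise every stage meaningfully on one CPU: detector training on
500 patches/class (32×32) for 30 epochs from 28 normalized phantoms;
segmentation evaluated on 20 unseen phantoms at patch 32 / stride 4;
classification on ages 5–10, 20 phantoms per class (vision-pipelined with
their exact ground-truth masks so the stage is assessed in isolation),
60 epochs × 3 restarts at batch 8, learning rate 0.01, gamma 0.5, evaluated
on a fresh 10-per-class held-out batch; occlusion localization pooled over
correctly classified held-out phantoms with a 24-px occluder (roughly the
physis thickness plus margins at the 224-px ingestion scale).

## Numerical and testing notes

The CNN engine is float32 numpy (im2col convolutions); every layer's
backward pass is verified against float64 central differences in the test
suite. All randomness flows through explicit `numpy.random.Generator`
seeds; identical seeds give bit-identical training trajectories on a given
platform, which is what makes the end-to-end determinism check meaningful.
A `BatchNorm2D` layer exists in the engine (gradient-checked) but the
default backbones do not use it; at desk-scale batch sizes it did not
improve trainability. Degenerate inputs are defined behaviors: constant
images pass through equalization as constants, empty masks raise
segmentation errors, patch/occluder sizes larger than the image raise
geometry errors, and a failed segmentation inside the patch/stride sweep
scores IoU 0 rather than aborting the sweep.

The augmentation non-inferiority check (augmented vs unaugmented validation
accuracy at matched epochs, five seeds) uses a desk-scaled grid (rotation
±3°, shear ±2°, resize 0.97–1.0): the full clinical grids assume thousands
of training images, and at a few dozen phantoms ±30° rotations dominate the
within-class variation they are meant to regularize.

## Known limitations

The printed product of the default augmentation grids is 110,715,000
(61·150·121·100). Desk-scale training is intentionally small: absolute
accuracies on phantoms say nothing quantitative about clinical data. The
full-size backbone is provided but not exercised by the test suite. No
ImageNet-pretrained weights are distributed, so the transfer-learning
pathway (fine-tuning depths with a pretrained initialization) is exercised
mechanically (freeze semantics, filter conversion) rather than scientifically.
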