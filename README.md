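# autobaa — fully automated bone-age assessment from hand radiographs

Skeletal maturity ("bone age") is read from a left-hand/wrist radiograph by
comparing it against reference stages; pediatric endocrinology uses the gap
between bone age and chronological age to work up growth disorders. Manual
reading against an atlas is slow and has substantial interobserver
variability. `autobaa` implements a fully automated deep-learning pipeline
for this task, aimed at researchers who want a reproducible, testable
implementation of every stage:

1. **Normalization** — radiographs arrive black-on-white or white-on-black
   at wildly varying sizes. A four-corner brightness test (mean of four
   10×10 corner patches vs `2^bits / 2`) standardizes the grayscale base to
   black-background; aspect-preserving resize plus symmetric zero padding
   yields 512×512 images.
2. **Detection CNN** — a LeNet-5-style patch classifier scores 32×32 patches
   into the five objects on a radiograph: bone, tissue, background,
   collimation, annotation markers. Trained on class-balanced patch samples
   (label = ground-truth class of the patch center).
3. **Segmentation** — the detector slides across the image (stride 4); each
   pixel takes the argmax of the mean score vector of all covering patches.
   Bone+tissue pixels form the hand; the largest 4-connected component,
   hole-filled, is the hand mask. Quality is measured as mean
   Intersection-over-Union (mIoU) against ground-truth masks.
4. **Vision pipeline** — mask the image, center the hand, equalize contrast
   over in-mask pixels, median-denoise, unsharp-sharpen.
5. **Classification CNN** — an inception-style network assigns one of 14
   integer bone-age classes (5…18 years; separate models per sex), trained
   with SGD (momentum 0.9, weight decay 0.005, stepped learning rate) and
   on-line data augmentation drawn from finite grids (61 rotations ×
   150 resizes × 121 shears × 100 pixel transforms = 110,715,000 distinct
   images per input). Layer-wise fine-tuning depth (`fc` → … → `conv1` →
   `all`/`scratch`) is controllable, and a 3×3 learning-rate/gamma grid
   search mirrors the original training protocol.
6. **Attention maps** — occlusion sensitivity: slide a zero-filled occluder,
   record the drop in the true class probability per position.
7. **Reports** — a structured report with the predicted age, maturity stage
   (prepuberty / early-mid / late / postpuberty, sex-specific bins) and the
   top-3…5 reference-age suggestions with probabilities.

No clinical images ship with the package. A **synthetic phantom generator**
(`autobaa.phantom`) renders hand-like radiographs with exact per-pixel
ground truth and an age-dependent signal — radiolucent growth-plate gaps in
every finger bone and the distal radius/ulna whose width shrinks linearly
with the age class and closes at 18 — so the whole pipeline is exercisable
and testable end to end.

## Worked example

Train a patch detector on phantoms, a bone-age classifier from a manifest of
preprocessed labeled images (here: 12 vision-pipelined phantoms per age
class 5–10, female), then run the deployed pipeline on a new radiograph:

```bash
autobaa train-detector --images-per-class 1 --n-per-class 500 \
    --epochs 30 --seed 11 --out detector.npz
# -> detector saved to detector.npz (validation accuracy 0.981)
autobaa train-classifier --manifest train_manifest.csv --sex female \
    --epochs 60 --base-lr 0.01 --gamma 0.5 --batch-size 8 \
    --no-augment --restarts 3 --seed 7 --out classifier.npz
# -> classifier saved to classifier.npz (best validation accuracy 0.500)
autobaa predict --in case.png --detector-model detector.npz \
    --classifier-model classifier.npz --sex female --format text
```

where `case.png` is a held-out white-background phantom of age class 9.
This prints (timestamp aside) exactly:

```
BONE AGE ASSESSMENT (automated)
study:            case
sex:              female
predicted age:    9 years
maturity stage:   early-mid-puberty
reference suggestions:
   9 years   p = 0.479
   8 years   p = 0.277
  10 years   p = 0.244
   7 years   p = 0.000
   6 years   p = 0.000
generated: 2026-09-27T19:31:08.107177+00:00
```

The predicted age is the argmax over the 14 classes; the suggestion rows
are the top-5 classes by probability (the radiologist-facing shortlist of
atlas pages to compare); the maturity stage is the sex-specific bin of the
predicted age. Repeated runs on the same input and model files produce the
identical report (up to the timestamp).

The same stages are available as a library: `autobaa.pipeline.preprocess`,
`autobaa.classifier.BoneAgeCNN` (a scikit-learn-style estimator),
`autobaa.evaluation.occlusion_map`, `autobaa.report.run_pipeline`.

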