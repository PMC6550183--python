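# Methods

## Problem and model

`pillpipe` identifies prescription pills in RGB photographs in two stages.

**Stage 1 — localization.** Pill detection is cast as binary semantic
segmentation: a fully convolutional network (no dense layers anywhere)
maps an `H×W×3` image to an `H×W×1` per-pixel probability through a final
sigmoid. The training loss is pixel-wise binary cross-entropy with
per-pixel weights

    L = mean_i  w_i · BCE(p_i, t_i),      w_i ∈ {1, 2},

where `w_i = 2` on the band of pixels within Chebyshev distance `band_px`
(default 5) of the mask's inner boundary (foreground pixels 8-adjacent to
background) and 1 elsewhere. Doubling the boundary weight penalizes sloppy
outlines, which matters because the downstream crop is the component's
tight box. Predictions are clipped to `[ε, 1−ε]`, `ε = 10⁻⁷`.

Optimization: Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 10⁻³ for
the detector. Whenever the validation loss fails to improve by more than
`min_delta` (10⁻⁴) for `plateau_patience` (3) consecutive epochs the
learning rate is multiplied by 0.2; training stops after
`early_stop_patience` epochs without improvement. The learning-rate trace
is therefore non-increasing and every change is exactly ×0.2.

Mask post-processing: binarize at 0.5; remove small blobs with a square
10 px structuring element; for consumer-style photos additionally dilate
by a square 10 px element so slightly tight masks do not cut pills off;
extract 8-connected components. Each component becomes a detection whose
box is the component's tight half-open box and whose confidence is the
mean predicted probability over the component's pixels (bounded, monotone
in model certainty). The cleanup step defaults to *morphological opening*:
opening is the operation that removes foreground blobs smaller than the
element, which is the step's stated purpose; a `cleanup="closing"` switch
runs the literal alternative for comparison.

**Stage 2 — classification.** A detection is cropped as a rectangle —
deliberately *not* masked to the pill contour — so the background texture
and lighting context remain visible to the classifier. The shorter side is
padded symmetrically to a square (odd remainder: extra pixel on
bottom/right; padding replicates edge pixels to avoid introducing an
artificial border color) and the square is resized bilinearly to 224×224.
Content aspect ratio is preserved exactly.

The classifier is an ImageNet-style backbone truncated at its final global
average pooling, topped with two blocks of batch-norm → drop-out → dense.
Both dense layers have width `n_classes` (first ReLU, second softmax) and
both drop-out layers share one rate. This head reconstruction reproduces
the published total parameter counts of the reference models exactly:

| backbone       | trunk params | head (924 classes) | total      |
|----------------|-------------:|-------------------:|-----------:|
| ResNet50       | 23,587,712   | 2,759,864          | 26,347,576 |
| MobileNet v1   |  3,228,864   | 1,809,592          |  5,038,456 |
| SqueezeNet v1.1|    722,496   | 1,334,456          |  2,056,952 |

SqueezeNet is the v1.1 variant (its 722,496-parameter trunk is the one
consistent with the 2.06 M total; v1.0 is not). InceptionV3 is built by
the same uniform rule (2048-wide pooled features → 24,562,648 total at 924
classes); its published 26.56 M figure is not reproduced by any head
consistent with the other three models, so it is excluded from the
parameter-count checks. Batch-norm statistics (moving mean/variance) are
included in all counts, as frameworks report them.

Class labels are National Drug Codes: appearance categories sharing an NDC
merge into one class, and class indices are assigned by sorted NDC string.

**Hyper-parameter search.** Drop-out rate × initial learning rate over
`{0.2, 0.4} × {5·10⁻⁵, 10⁻⁴, 5·10⁻⁴}` (6 configurations), evaluated by
fourfold cross-validation: consumer items are partitioned into 4
class-stratified folds; reference items join every training fold and never
a validation fold (evaluation always targets consumer-style imagery). The
winning configuration maximizes mean top-5 accuracy; ties break by higher
mean top-1, then lower learning rate. A stratified 20% of consumer items
is held out of everything and used only for final evaluation.

**Evaluation.** Top-k accuracy breaks score ties by ascending class index
(deterministic). Micro-averaged precision-recall pools all one-vs-rest
(score, indicator) pairs across classes and sweeps every distinct score
threshold; average precision is the step-wise sum `AP = Σ (Rᵢ−Rᵢ₋₁)·Pᵢ`
with no interpolation smoothing (the standard modern definition; verified
against brute-force enumeration and scikit-learn in the tests). Per-class
AP is the same sweep one class at a time; classes without positives are
excluded with a warning. Grouped confusion matrices aggregate predictions
by a class attribute (color or shape): rows are the true attribute,
columns the predicted one. Penultimate features — the activations
immediately before the first head dense layer (2048-wide for ResNet50) —
can be exported for external embedding tools such as t-SNE.

## Synthetic data generator

The generator emulates the two image sources of pill-recognition datasets.

*Reference style*: a single pill on a uniform gray background of RGB
(117, 117, 117). Keying treats a pixel as background when every channel is
within ±1 (per-channel tolerance, configurable) of the key color; the pill
is the largest 8-connected foreground component, tight-cropped into a
sprite with a binary alpha mask.

*Consumer style*: 1–5 pills composited onto textured backgrounds with
per-pill uniform sampling of rotation in [0°, 360°), scale such that the
rotated alpha box's max dimension is uniform in [20, 50] px, and a drop
shadow offset uniform in [0, 20] px. These ranges are the generator's
defaults at the native 480×640 canvas. Runtime augmentations (brightness,
contrast, Gaussian blur, affine and perspective warps) apply photometric
transforms to the image only and geometric transforms to image and mask
identically, re-binarizing the mask at 0.5; the fully degenerate
configuration is the bit-exact identity.

Decisions the composite model had to fix:

* **Overlap** — a placement is rejected if the new pill's mask intersects
  any existing instance mask, with up to 30 retries before a
  `PlacementFailed` error. Non-overlapping pills keep every ground-truth
  box unambiguous.
* **Shadow** — the instance mask shifted by the sampled offset in a
  direction uniform in [0°, 360°), Gaussian-blurred with σ = max(offset/3, 1),
  composited by multiplying the background by (1 − 0.5·blur) before the
  pill is pasted. Visually plausible and fully deterministic per seed.
* **Backgrounds** — procedural textures (flat colors, Gaussian noise,
  stripes, wood-like gradients, paper) replace photographed office
  surfaces, removing all external-data dependencies.
* **Interpolation** — sprite color channels resize bilinearly; alpha masks
  resize nearest / threshold-0.5 so masks stay strictly binary.
* **Randomness** — one seeded generator per dataset; scene *i* uses the
  substream seeded by `(dataset_seed, i)`, so any single scene is
  reproducible in isolation.
* **Coordinates** — 0-based, row-major; boxes half-open `[r0,r1)×[c0,c1)`,
  stated once and used everywhere.

What the generator does *not* model: photo-realistic shading, specular
highlights on gel capsules, camera noise profiles, perspective foreshortening
of the scene plane, and real pharmacy imprint fonts. Passing tests on this
data therefore demonstrate that the pipeline's machinery (training loop,
morphology, standardization, metrics, service plumbing) is correct — not
that the small test networks would reach any particular accuracy on real
consumer photographs, which requires the full-scale dataset and
ImageNet-pretrained backbones.

## Numerical engine and scaled-down study sizes

The networks run on a small numpy engine (NHWC layout; convolution as a
sum of k² strided matmuls, so no im2col buffer materializes; manual
backpropagation; Adam; inverted drop-out; batch-norm with momentum-0.9
moving statistics for the small trainable models). The four reference
backbones are assembled from the same primitives for inference and exact
parameter accounting; fine-tuning at ImageNet scale is out of scope, and
`pretrained=True` loads weights from a user-supplied `.npz` checkpoint
rather than bundling any.

Experiment sizes are chosen for a single CPU core:

* **Detector study** — the trainable FCN is a 4-level encoder–decoder
  (width 12; two 2×2 max-pools mirrored by nearest upsampling; overall
  stride 4; sigmoid output at input resolution) trained on 200 scenes at
  96×128 with the generator's ranges scaled proportionally (1–3 pills,
  8–20 px size, 0–4 px shadow), 40 held-out scenes, batch size 4,
  initial learning rate 10⁻³. Held-out mean IoU of the thresholded union
  mask is the headline number (≥ 0.8 under these conditions).
* **Classifier study** — 10 NDC classes × 100 crops (75% consumer-style,
  25% reference-style, mirroring the dataset's roughly 5:2 makeup),
  70/10/20 train/val/hold-out, SMALL_TEST backbone (stride-4 stem, 96-wide
  pooled features), drop-out 0.2, initial learning rate 10⁻³, batch 32, up
  to 40 epochs.  Hold-out top-1/top-5 and micro-AP are reported.  Training
  restores the best-validation epoch's weights when it stops (both stages).

Degenerate inputs are defined rather than left to chance: an all-zero mask
yields unit loss weights and an empty detection list; an empty/empty mask
pair has IoU 1; top-k with k above the class count clamps with a warning;
a probability mask outside [0, 1] is rejected.

## Known limitations

* The big backbones are inference/accounting structures; only the small
  variants train (CPU-scale). The training loop itself is identical.
* Nearest-neighbour upsampling (not learned deconvolution) in both FCN
  decoders; adequate at these scales, blockier at 32× upsampling.
* The rotation-alignment step sketched for the identification input is
  not implemented anywhere in the source pipeline's text and is omitted;
  crops keep the detector's axis-aligned box orientation.
* The NLM challenge metadata adapter (`load_category_manifest`) expects a
  local CSV; the real 1000-category table is not bundled, so the
  challenge-scale NDC merge is exercised on a synthetic stand-in manifest
  with the same shape (1000 categories, 924 distinct codes).
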