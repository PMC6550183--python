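# pillpipe

Automatic medication identification from photographs. Given an image
containing one or more pills, `pillpipe` locates each pill, standardizes the
crop, and ranks candidate **National Drug Codes** (NDC) — the 10–11 digit
product identifiers used for US medications — by confidence.

The pipeline has two stages:

1. **Localization.** A fully convolutional network (FCN) maps an
   `H × W × 3` image to an `H × W × 1` sigmoid probability mask
   (pill vs background). Training minimizes a boundary-weighted binary
   cross-entropy — pixels within a band around each pill outline carry
   twice the loss weight, the U-Net trick for sharp boundaries:

   `L = (1/N) Σᵢ wᵢ · [−tᵢ log pᵢ − (1−tᵢ) log(1−pᵢ)]`, with `wᵢ ∈ {1, 2}`.

   Predicted masks are binarized, cleaned with a 10 px morphological kernel,
   optionally dilated by 10 px (consumer-style photos, to avoid cutting
   pills off), and 8-connected components become scored bounding boxes.
2. **Classification.** Each detection is cropped *with its background* (no
   contour segmentation, preserving lighting context), padded to square and
   resized to 224 × 224. A CNN backbone truncated at its final global
   average pooling (ResNet50, MobileNet, SqueezeNet v1.1, InceptionV3, or a
   small CPU-friendly test network) feeds two blocks of
   batch-norm → drop-out → dense; the first dense is ReLU, the second a
   softmax over the merged NDC classes. The drop-out rate and Adam initial
   learning rate are searched over `{0.2, 0.4} × {5·10⁻⁵, 10⁻⁴, 5·10⁻⁴}`
   with fourfold cross-validation; both stages reduce the learning rate by
   ×0.2 on validation-loss plateaus.

Because segmentation training data with pixel-exact masks is expensive, the
detector trains on **procedurally composited scenes**: pill sprites (keyed
from uniform-gray reference images, or drawn synthetically) are placed on
textured backgrounds with 1–5 pills per image, full 360° rotation,
20–50 px pill size, and 0–20 px drop shadows, yielding exact per-instance
ground truth. The same generator emulates reference- and consumer-style
crops for classifier experiments, so everything here runs end-to-end
without any external download.

## Worked example

```python
import numpy as np
from pillpipe.synthetic_data import (SceneParams, compose_scene,
                                     make_background, make_default_catalog)
from pillpipe.localization import DetectorSpec, build_fcn, train_detector, \
    predict_mask, mask_to_detections
from pillpipe.nn.optim import TrainSchedule

params = SceneParams(n_pills_range=(2, 2), pill_size_px_range=(14, 20),
                     canvas=(96, 128))
pool = make_default_catalog(base_size=48, seed=0)
rng = np.random.default_rng(21)
scene = compose_scene(pool, make_background("paper", (96, 128), rng),
                      params, rng)
print(len(scene.boxes), scene.boxes)
```

```
2 [(35, 79, 54, 98), (68, 33, 84, 49)]
```

Two pills were composited; their tight half-open boxes `[r0,r1)×[c0,c1)`
are exact ground truth. After training the small detector on 200 such
scenes (see `scripts/acceptance.py`), `predict_mask` + `mask_to_detections`
recovers boxes covering these, each with a confidence in `[0, 1]`, and the
classifier ranks NDCs for every crop. The same flow is exposed over HTTP
(`pillpipe serve`, endpoints `/detect` and `/identify`; response schemas in
`schemas/`) and on the command line (`pillpipe synth | train-detector |
detect | crop | train-classifier | predict | evaluate | serve`).

## Layout

```
src/pillpipe/
  synthetic_data.py   # sprites, reference keying, scene compositing, augments
  localization.py     # FCN spec/training, boundary-weighted loss, blob boxes
  standardize.py      # crop -> pad-to-square -> 224x224
  classifier.py       # NDC label map, head surgery, fine-tuning, grid search
  evaluation.py       # splits, top-k, micro/per-class AP, grouped confusion
  service.py, cli.py  # WSGI endpoints and command-line interface
  nn/                 # numpy layers, backbones, Adam + plateau schedule
```

See `docs/methods.md` for the modelling and design notes.
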