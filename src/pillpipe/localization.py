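"""Pill localization: FCN blob detector plus morphological post-processing.

The detector is a fully convolutional network mapping an H x W x 3 image to
an H x W x 1 sigmoid probability mask (pill vs background).  Training uses a
boundary-weighted binary cross-entropy: pixels within a band around each pill
outline carry twice the loss weight, sharpening mask edges.  Predicted masks
are binarized, cleaned with a 10 px morphological kernel, optionally dilated
(consumer images, to avoid cutting pills off), and 8-connected components
become scored bounding boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, dilation, opening

from .errors import InvalidArgument
from .nn.backbones import FCNVGG16, small_fcn
from .nn.layers import Dense, Sigmoid
from .nn.model import Sequential
from .nn.optim import Adam, History, PlateauTracker, TrainSchedule

_EPS = 1e-7


@dataclass
class DetectorSpec:
    """Contract for the segmentation network."""
    input_shape: tuple[int, int, int] = (480, 640, 3)
    backbone: str = "vgg16_fcn8s"       # or "small" (trainable CPU variant)
    pretrained: bool = False
    weights_path: str | None = None
    width: int = 12                     # channel width of the small variant
    seed: int = 0

    @property
    def output_shape(self):
        return (self.input_shape[0], self.input_shape[1], 1)


@dataclass
class Detection:
    """One localized pill: half-open box [r0, r1) x [c0, c1) and confidence."""
    box: tuple[int, int, int, int]
    score: float


@dataclass
class Detector:
    net: Sequential
    spec: DetectorSpec

    def predict(self, image: np.ndarray) -> np.ndarray:
        return predict_mask(self, image)


_STRIDES = {"vgg16_fcn8s": 32, "small": 4}


def build_fcn(spec: DetectorSpec) -> Detector:
    """Build the segmentation FCN per ``spec``.

    The network contains no dense layers and ends in a sigmoid, so the output
    probability mask has the input's spatial size.  ``pretrained=True``
    initializes encoder weights from a serialized ``.npz`` checkpoint given in
    ``weights_path`` (ImageNet-derived weights are external artifacts and are
    not bundled).
    """
    h, w, c = spec.input_shape
    if c != 3:
        raise InvalidArgument("detector input must have 3 channels")
    if spec.backbone not in _STRIDES:
        raise InvalidArgument(f"unknown detector backbone {spec.backbone!r}")
    stride = _STRIDES[spec.backbone]
    if h % stride or w % stride:
        raise InvalidArgument(
            f"input {h}x{w} not divisible by encoder stride {stride}")
    rng = np.random.default_rng(spec.seed)
    if spec.backbone == "vgg16_fcn8s":
        net = FCNVGG16(rng=rng)
    else:
        net, _ = small_fcn(rng=rng, width=spec.width)
    assert not any(isinstance(l, Dense) for l in _flat_layers(net)), \
        "FCN must not contain fully connected layers"
    assert isinstance(_flat_layers(net)[-1], Sigmoid)
    if spec.pretrained:
        if not spec.weights_path:
            raise InvalidArgument(
                "pretrained=True requires weights_path (pretrained weights "
                "are not bundled with the package)")
        with np.load(spec.weights_path) as data:
            net.set_weights(dict(data))
    return Detector(net=net, spec=spec)


def _flat_layers(layer):
    if isinstance(layer, Sequential):
        out = []
        for sub in layer.layers:
            out.extend(_flat_layers(sub))
        return out
    return [layer]


# ------------------------------------------------------------------- loss --

def boundary_weight_map(mask: np.ndarray, band_px: int = 5,
                        factor: float = 2.0) -> np.ndarray:
    """Per-pixel loss weights: ``factor`` in a band around pill boundaries.

    The boundary is the set of foreground pixels 8-adjacent to background;
    the band is every pixel within Chebyshev distance ``band_px`` of that
    set (which always includes the adjacent background pixels).  All other
    pixels weigh 1.0.
    """
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.isin(uniq, (0, 1)).all():
        raise InvalidArgument("mask must be binary (0/1)")
    if band_px < 1:
        raise InvalidArgument("band_px must be >= 1")
    m = mask.astype(bool)
    weights = np.ones(m.shape, dtype=np.float32)
    if not m.any() or m.all():
        return weights
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=1)
    inner_boundary = m & ~eroded
    band = ndimage.binary_dilation(
        inner_boundary, structure=np.ones((2 * band_px + 1, 2 * band_px + 1)))
    weights[band] = factor
    return weights


def weighted_pixel_loss(pred: np.ndarray, target: np.ndarray,
                        weights: np.ndarray) -> float:
    """Mean over pixels of ``weights * BCE(pred, target)`` with clipped preds."""
    pred, target, weights = (np.asarray(a, dtype=np.float64)
                             for a in (pred, target, weights))
    if not (pred.shape == target.shape == weights.shape):
        raise InvalidArgument("pred/target/weights shapes differ")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    bce = -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    return float(np.mean(weights * bce))


# --------------------------------------------------------------- training --

def _as_arrays(data):
    if isinstance(data, str):
        from .synthetic_data import load_manifest_arrays
        images, masks, _ = load_manifest_arrays(data)
        return images, masks
    images, masks = data
    return np.asarray(images), np.asarray(masks)


def train_detector(detector: Detector, train_manifest, val_manifest,
                   schedule: TrainSchedule = None, band_px: int = 5,
                   seed: int = 0) -> tuple[Detector, History]:
    """Fit the detector with Adam and the x0.2 plateau schedule.

    ``train_manifest``/``val_manifest`` are either dataset directories written
    by :func:`pillpipe.synthetic_data.generate_dataset` or ``(images, masks)``
    array pairs at the detector's input size.  The history logs per-epoch
    train/validation loss and the learning rate; the rate only ever changes
    by the plateau factor.  On return the detector carries the weights of
    its best-validation epoch.
    """
    schedule = schedule or TrainSchedule(initial_lr=1e-3)
    x_tr, y_tr = _as_arrays(train_manifest)
    x_va, y_va = _as_arrays(val_manifest)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise InvalidArgument("empty training or validation manifest")
    h, w, _ = detector.spec.input_shape
    if x_tr.shape[1:3] != (h, w):
        raise InvalidArgument(
            f"training images are {x_tr.shape[1:3]}, detector expects {(h, w)}")
    x_tr = x_tr.astype(np.float32) / 255.0
    x_va = x_va.astype(np.float32) / 255.0
    y_tr = y_tr.astype(np.float32)[..., None]
    y_va = y_va.astype(np.float32)[..., None]
    w_tr = np.stack([boundary_weight_map(y[..., 0].astype(np.uint8), band_px)
                     for y in y_tr])[..., None]
    w_va = np.stack([boundary_weight_map(y[..., 0].astype(np.uint8), band_px)
                     for y in y_va])[..., None]

    net = detector.net
    layers_to_logits = net.layers[:-1]
    assert isinstance(net.layers[-1], Sigmoid)

    opt = Adam(net.params(), lr=schedule.initial_lr,
               beta1=schedule.beta1, beta2=schedule.beta2)
    tracker = PlateauTracker(schedule)
    history = History()
    rng = np.random.default_rng(seed)
    n = len(x_tr)
    bs = schedule.batch_size

    def _forward_logits(xb, training):
        z = xb
        for layer in layers_to_logits:
            z = layer.forward(z, training=training)
        return z

    def _val_loss():
        total, count = 0.0, 0
        for i in range(0, len(x_va), bs):
            p = 1.0 / (1.0 + np.exp(-_forward_logits(x_va[i:i + bs], False)))
            sl = slice(i, i + bs)
            total += weighted_pixel_loss(p, y_va[sl], w_va[sl]) * len(p)
            count += len(p)
        return total / count

    best_val, best_weights = np.inf, None
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(n)
        train_loss, seen = 0.0, 0
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            xb, yb, wb = x_tr[idx], y_tr[idx], w_tr[idx]
            opt.zero_grad()
            logits = _forward_logits(xb, True)
            p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
            loss = weighted_pixel_loss(p, yb, wb)
            grad = (wb * (p - yb) / p.size).astype(np.float32)
            for layer in reversed(layers_to_logits):
                grad = layer.backward(grad)
            opt.step()
            train_loss += loss * len(xb)
            seen += len(xb)
        val_loss = _val_loss()
        history.log(epoch=epoch, lr=opt.lr, train_loss=train_loss / seen,
                    val_loss=val_loss)
        if val_loss < best_val:
            best_val, best_weights = val_loss, net.get_weights()
        reduce, stop = tracker.update(val_loss)
        if reduce:
            opt.lr *= schedule.plateau_factor
        if stop:
            break
    if best_weights is not None:  # keep the best-validation epoch's weights
        net.set_weights(best_weights)
    return detector, history


def predict_mask(detector: Detector, image: np.ndarray) -> np.ndarray:
    """Run inference; returns an (H, W) probability mask in [0, 1]."""
    image = np.asarray(image)
    h, w, _ = detector.spec.input_shape
    if image.shape[:2] != (h, w) or image.ndim != 3:
        raise InvalidArgument(
            f"image shape {image.shape} does not match detector input {(h, w, 3)}")
    x = image.astype(np.float32)[None] / 255.0
    out = detector.net.forward(x, training=False)
    return out[0, :, :, 0]


# ---------------------------------------------------------- blob -> boxes --

def mask_to_detections(prob_mask: np.ndarray, threshold: float = 0.5,
                       cleanup_kernel_px: int = 10, consumer_dilate_px: int = 10,
                       consumer_mode: bool = False,
                       cleanup: str = "opening") -> list[Detection]:
    """Convert a probability mask into scored bounding boxes.

    Binarize at ``threshold``; remove small blobs with a square
    ``cleanup_kernel_px`` morphological kernel (``cleanup='opening'`` by
    default — an opening is the operation that actually removes blobs smaller
    than the kernel; ``'closing'`` is available as an alternative reading);
    in ``consumer_mode``, dilate blobs by a square ``consumer_dilate_px``
    kernel before component extraction so tight predictions do not cut pills
    off.  Each 8-connected component yields a Detection whose score is the
    mean predicted probability over the component's pixels.  Results are
    sorted by score descending, ties broken by (r0, c0).
    """
    prob = np.asarray(prob_mask, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise InvalidArgument("probability mask values must lie in [0, 1]")
    binary = prob >= threshold
    if cleanup_kernel_px > 1:
        footprint = np.ones((cleanup_kernel_px, cleanup_kernel_px), dtype=bool)
        op = {"opening": opening, "closing": closing}.get(cleanup)
        if op is None:
            raise InvalidArgument(f"cleanup must be opening|closing, got {cleanup!r}")
        binary = op(binary, footprint)
    if consumer_mode and consumer_dilate_px > 1:
        binary = dilation(
            binary, np.ones((consumer_dilate_px, consumer_dilate_px), dtype=bool))
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    detections = []
    for lab in range(1, n + 1):
        comp = labels == lab
        rows = np.flatnonzero(comp.any(axis=1))
        cols = np.flatnonzero(comp.any(axis=0))
        box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        score = float(prob[comp].mean())
        detections.append(Detection(box=box, score=score))
    detections.sort(key=lambda d: (-d.score, d.box[0], d.box[1]))
    return detections


# ------------------------------------------------------------- evaluation --

def mask_iou(pred_binary: np.ndarray, true_binary: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (empty/empty -> 1.0)."""
    p, t = np.asarray(pred_binary, bool), np.asarray(true_binary, bool)
    union = (p | t).sum()
    if union == 0:
        return 1.0
    return float((p & t).sum() / union)


def mean_mask_iou(detector: Detector, images, masks, threshold=0.5) -> float:
    """Mean IoU of thresholded predictions against ground-truth union masks."""
    scores = [mask_iou(predict_mask(detector, img) >= threshold, m)
              for img, m in zip(images, masks)]
    return float(np.mean(scores))


def save_history(history: History, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(history.to_json(), fh, indent=1)


def save_detector(detector: Detector, prefix: str) -> None:
    """Serialize weights (npz) and spec (json) under ``prefix``."""
    np.savez(prefix + ".npz", **detector.net.get_weights())
    spec = detector.spec
    with open(prefix + ".json", "w") as fh:
        json.dump({"input_shape": list(spec.input_shape),
                   "backbone": spec.backbone, "width": spec.width,
                   "seed": spec.seed}, fh)


def load_detector(prefix: str) -> Detector:
    with open(prefix + ".json") as fh:
        d = json.load(fh)
    det = build_fcn(DetectorSpec(input_shape=tuple(d["input_shape"]),
                                 backbone=d["backbone"], width=d["width"],
                                 seed=d["seed"]))
    with np.load(prefix + ".npz") as data:
        det.net.set_weights(dict(data))
    return det
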