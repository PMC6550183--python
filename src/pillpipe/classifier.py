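"""NDC classification: label merging, CNN head surgery, fine-tuning, search.

Labels are National Drug Codes (NDC): appearance categories that share an
NDC merge into a single class.  Each classifier is an ImageNet-style
backbone truncated at its final global average pooling, topped with two
blocks of (batch-norm, drop-out, dense); the first dense is ReLU, the second
softmax over the NDC classes.  Both drop-out layers share one rate, which —
together with the Adam initial learning rate — forms the hyper-parameter
grid searched by fourfold cross-validation on consumer items (reference
items join every training fold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import InvalidArgument, ValidationError
from .nn.backbones import BACKBONES
from .nn.layers import BatchNorm, Dense, Dropout, ReLU
from .nn.model import Sequential
from .nn.optim import Adam, History, PlateauTracker, TrainSchedule


# -------------------------------------------------------------- label map --

@dataclass
class NDCLabelMap:
    category_to_ndc: dict[str, str]
    ndc_to_index: dict[str, int]

    @property
    def n_classes(self) -> int:
        return len(self.ndc_to_index)

    def index_to_ndc(self, idx: int) -> str:
        return self._index_list[idx]

    def __post_init__(self):
        self._index_list = [None] * len(self.ndc_to_index)
        for ndc, i in self.ndc_to_index.items():
            self._index_list[i] = ndc

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"category_to_ndc": self.category_to_ndc,
                       "ndc_to_index": self.ndc_to_index}, fh, indent=1,
                      sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "NDCLabelMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(category_to_ndc=d["category_to_ndc"],
                   ndc_to_index={k: int(v) for k, v in d["ndc_to_index"].items()})


def build_ndc_label_map(category_manifest) -> NDCLabelMap:
    """Merge appearance categories that share an NDC into single classes.

    ``category_manifest`` is an iterable of ``(category_id, ndc)`` pairs,
    dicts with those keys, or a pandas DataFrame with those columns.  Class
    indices are assigned by sorted NDC string.  Categories with a missing or
    blank NDC raise a :class:`ValidationError` listing every offender.
    """
    rows = []
    if hasattr(category_manifest, "itertuples"):  # DataFrame
        rows = [(str(r.category_id), r.ndc)
                for r in category_manifest.itertuples(index=False)]
    else:
        for item in category_manifest:
            if isinstance(item, dict):
                rows.append((str(item["category_id"]), item.get("ndc")))
            else:
                cat, ndc = item
                rows.append((str(cat), ndc))
    bad = [cat for cat, ndc in rows
           if ndc is None or (isinstance(ndc, float) and np.isnan(ndc))
           or not str(ndc).strip()]
    if bad:
        raise ValidationError(f"categories with missing/blank NDC: {bad}")
    category_to_ndc = {cat: str(ndc).strip() for cat, ndc in rows}
    ndcs = sorted(set(category_to_ndc.values()))
    return NDCLabelMap(category_to_ndc=category_to_ndc,
                       ndc_to_index={ndc: i for i, ndc in enumerate(ndcs)})


def load_category_manifest(path: str):
    """Adapter for challenge-style metadata: CSV with category_id,ndc columns."""
    import pandas as pd
    df = pd.read_csv(path, dtype=str)
    return df[["category_id", "ndc"]]


# ------------------------------------------------------------------ model --

@dataclass
class ClassifierSpec:
    backbone: str = "SMALL_TEST"
    n_classes: int = 10
    dropout_rate: float = 0.2
    pretrained: bool = False
    weights_path: str | None = None
    input_size: int = 224
    seed: int = 0


@dataclass
class Classifier:
    backbone: Sequential
    head: Sequential            # up to the final logits (softmax applied here)
    spec: ClassifierSpec
    feature_width: int

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x, training=training),
                                 training=training)

    def predict_proba(self, crops: np.ndarray, batch_size: int = 32) -> np.ndarray:
        crops = np.asarray(crops)
        if crops.ndim == 3:
            crops = crops[None]
        out = []
        for i in range(0, len(crops), batch_size):
            x = crops[i:i + batch_size].astype(np.float32) / 255.0
            out.append(_softmax(self.forward_logits(x, training=False)))
        return np.concatenate(out, axis=0)

    def features(self, crops: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Activations immediately before the first head dense layer."""
        crops = np.asarray(crops)
        if crops.ndim == 3:
            crops = crops[None]
        out = []
        for i in range(0, len(crops), batch_size):
            x = crops[i:i + batch_size].astype(np.float32) / 255.0
            z = self.backbone.forward(x, training=False)
            for layer in self.head.layers:
                if isinstance(layer, Dense):
                    break
                z = layer.forward(z, training=False)
            out.append(z)
        return np.concatenate(out, axis=0)

    def params(self):
        return self.backbone.params() + self.head.params()


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_classifier(spec: ClassifierSpec) -> Classifier:
    """Backbone truncated at its final pooling + two (BN, drop-out, dense) blocks.

    Both dense layers have width ``n_classes`` (first ReLU, second softmax)
    and both drop-out layers share ``spec.dropout_rate``.  ``pretrained=True``
    loads backbone weights from a serialized ``.npz`` at ``weights_path``
    (ImageNet weights are external artifacts, not bundled); the head is
    always randomly initialized from ``spec.seed``.
    """
    if spec.n_classes < 2:
        raise InvalidArgument("n_classes must be >= 2")
    if spec.backbone not in BACKBONES:
        raise InvalidArgument(f"unknown backbone {spec.backbone!r}; "
                              f"choose from {sorted(BACKBONES)}")
    rng = np.random.default_rng(spec.seed)
    backbone, width = BACKBONES[spec.backbone](rng=rng)
    if spec.pretrained:
        if not spec.weights_path:
            raise InvalidArgument(
                "pretrained=True requires weights_path (pretrained weights "
                "are not bundled with the package)")
        with np.load(spec.weights_path) as data:
            backbone.set_weights(dict(data))
    n = spec.n_classes
    head = Sequential([
        BatchNorm(width, momentum=0.9, name="head.bn1"),
        Dropout(spec.dropout_rate, seed=spec.seed + 1),
        Dense(width, n, rng=rng, name="head.fc1"),
        ReLU(),
        BatchNorm(n, momentum=0.9, name="head.bn2"),
        Dropout(spec.dropout_rate, seed=spec.seed + 2),
        Dense(n, n, rng=rng, name="head.fc2"),
    ], name="head")
    return Classifier(backbone=backbone, head=head, spec=spec,
                      feature_width=width)


def count_parameters(model) -> int:
    """Total parameter count, batch-norm statistics included."""
    if hasattr(model, "params"):
        return int(sum(p.size for p in model.params()))
    return int(sum(p.size for p in model))


# -------------------------------------------------------------- training --

@dataclass
class HyperParams:
    dropout_rate: float = 0.2
    initial_lr: float = 1e-4


DEFAULT_GRID = {"dropout_rate": (0.2, 0.4),
                "initial_lr": (5e-5, 1e-4, 5e-4)}


def expand_grid(grid: dict = None) -> list[HyperParams]:
    grid = grid or DEFAULT_GRID
    return [HyperParams(dropout_rate=d, initial_lr=lr)
            for d, lr in product(grid["dropout_rate"], grid["initial_lr"])]


def finetune(model: Classifier, train_set, val_set, hp: HyperParams = None,
             schedule: TrainSchedule = None, seed: int = 0
             ) -> tuple[Classifier, History]:
    """Train all layers with Adam at ``hp.initial_lr`` and the x0.2 plateau rule.

    ``train_set``/``val_set`` are ``(crops_uint8, labels)`` pairs.  The
    history logs loss, accuracy and learning rate per epoch; every LR change
    in the trace is exactly a multiplication by the plateau factor.  The
    returned model carries the weights of its best-validation epoch.
    """
    hp = hp or HyperParams()
    schedule = schedule or TrainSchedule(initial_lr=hp.initial_lr,
                                         batch_size=32)
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    x_tr, x_va = np.asarray(x_tr), np.asarray(x_va)
    y_tr, y_va = np.asarray(y_tr, dtype=int), np.asarray(y_va, dtype=int)
    n_classes = model.spec.n_classes
    for ys in (y_tr, y_va):
        if ys.size and (ys.min() < 0 or ys.max() >= n_classes):
            raise ValidationError(
                f"class index out of range 0..{n_classes - 1}")
    for layer in model.head.layers:
        if isinstance(layer, Dropout):
            layer.rate = hp.dropout_rate

    params = model.params()
    opt = Adam(params, lr=schedule.initial_lr, beta1=schedule.beta1,
               beta2=schedule.beta2)
    tracker = PlateauTracker(schedule)
    history = History()
    rng = np.random.default_rng(seed)
    bs = schedule.batch_size

    def _eval(x, y):
        loss, correct = 0.0, 0
        for i in range(0, len(x), bs):
            xb = x[i:i + bs].astype(np.float32) / 255.0
            logits = model.forward_logits(xb, training=False)
            p = _softmax(logits)
            yb = y[i:i + bs]
            loss += -np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)).sum()
            correct += (p.argmax(axis=1) == yb).sum()
        return loss / len(x), correct / len(x)

    best_val, best_weights = np.inf, None
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, correct = 0.0, 0
        for i in range(0, len(x_tr), bs):
            idx = order[i:i + bs]
            xb = x_tr[idx].astype(np.float32) / 255.0
            yb = y_tr[idx]
            for p in params:
                p.grad = None
            logits = model.head.forward(
                model.backbone.forward(xb, training=True), training=True)
            p_hat = _softmax(logits)
            onehot = np.zeros_like(p_hat)
            onehot[np.arange(len(yb)), yb] = 1.0
            ep_loss += -np.log(np.clip(p_hat[np.arange(len(yb)), yb],
                                       1e-12, None)).sum()
            correct += (p_hat.argmax(axis=1) == yb).sum()
            grad = ((p_hat - onehot) / len(yb)).astype(np.float32)
            grad = model.head.backward(grad)
            model.backbone.backward(grad)
            opt.step()
        val_loss, val_acc = _eval(x_va, y_va)
        history.log(epoch=epoch, lr=opt.lr, train_loss=ep_loss / len(x_tr),
                    train_acc=correct / len(x_tr), val_loss=float(val_loss),
                    val_acc=float(val_acc))
        if val_loss < best_val:
            best_val = float(val_loss)
            best_weights = (model.backbone.get_weights(),
                            model.head.get_weights())
        reduce, stop = tracker.update(float(val_loss))
        if reduce:
            opt.lr *= schedule.plateau_factor
        if stop:
            break
    if best_weights is not None:  # keep the best-validation epoch's weights
        model.backbone.set_weights(best_weights[0])
        model.head.set_weights(best_weights[1])
    return model, history


# ------------------------------------------------------------ grid search --

def grid_search_cv(model_family, cv_pool, grid: dict = None, k_folds: int = 4,
                   metric: str = "top5", seed: int = 0):
    """Fourfold-CV hyper-parameter search over the drop-out x LR grid.

    ``model_family`` is a trainer callable
    ``(hp, train_items, val_items) -> {"top1": float, "top5": float}``.
    ``cv_pool`` is a list of items (dicts) with at least ``label`` and
    ``is_consumer`` keys; consumer items are partitioned into ``k_folds``
    stratified folds while reference items join every training split.
    Returns ``(best_hp, table)`` where the table holds per-config fold scores
    and means; the best config maximizes mean top-5, ties broken by higher
    mean top-1, then lower initial learning rate.
    """
    from .evaluation import assign_folds

    configs = expand_grid(grid)
    consumer_idx = [i for i, it in enumerate(cv_pool) if it["is_consumer"]]
    reference_idx = [i for i, it in enumerate(cv_pool) if not it["is_consumer"]]
    labels = np.asarray([cv_pool[i]["label"] for i in consumer_idx])
    folds = assign_folds(labels, k_folds, seed=seed)

    fold_splits = []
    for k in range(k_folds):
        val = [consumer_idx[j] for j in np.flatnonzero(folds == k)]
        train = ([consumer_idx[j] for j in np.flatnonzero(folds != k)]
                 + reference_idx)
        train_classes = {cv_pool[i]["label"] for i in train}
        missing = {cv_pool[i]["label"] for i in val} - train_classes
        if missing:
            raise ValidationError(
                f"classes {sorted(missing)} absent from fold {k} training split")
        fold_splits.append((train, val))

    table = []
    for hp in configs:
        fold_scores = []
        for train, val in fold_splits:
            scores = model_family(hp, [cv_pool[i] for i in train],
                                  [cv_pool[i] for i in val])
            fold_scores.append({"top1": float(scores["top1"]),
                                "top5": float(scores["top5"])})
        table.append({
            "dropout_rate": hp.dropout_rate, "initial_lr": hp.initial_lr,
            "fold_scores": fold_scores,
            "mean_top1": float(np.mean([s["top1"] for s in fold_scores])),
            "mean_top5": float(np.mean([s["top5"] for s in fold_scores])),
        })
    key = "mean_top5" if metric == "top5" else "mean_top1"
    best_row = max(table, key=lambda r: (r[key], r["mean_top1"], -r["initial_lr"]))
    best = HyperParams(dropout_rate=best_row["dropout_rate"],
                       initial_lr=best_row["initial_lr"])
    return best, table


# -------------------------------------------------------------- inference --

@dataclass
class Prediction:
    """Ranked (ndc, confidence) pairs, confidences non-increasing."""
    entries: list[tuple[str, float]]

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def predict_topk(model: Classifier, crop: np.ndarray, label_map: NDCLabelMap,
                 k: int = 5) -> Prediction:
    """Top-k NDC predictions for one standardized crop.

    Classes are ranked by softmax confidence; ties break by ascending class
    index.  ``k`` larger than the class count is clamped with a warning.
    """
    crop = np.asarray(crop)
    if crop.shape != (model.spec.input_size, model.spec.input_size, 3):
        raise InvalidArgument(
            f"crop must be {model.spec.input_size}x{model.spec.input_size}x3, "
            f"got {crop.shape}")
    n = model.spec.n_classes
    if k > n:
        warnings.warn(f"k={k} clamped to n_classes={n}")
        k = n
    if k < 1:
        raise InvalidArgument("k must be >= 1")
    probs = model.predict_proba(crop[None])[0]
    order = np.lexsort((np.arange(n), -probs))[:k]
    return Prediction(entries=[(label_map.index_to_ndc(int(i)), float(probs[i]))
                               for i in order])


# ---------------------------------------------------------- serialization --

def save_classifier(model: Classifier, prefix: str) -> None:
    """Serialize weights (npz) and spec (json) under ``prefix``."""
    weights = {f"backbone/{k}": v for k, v in model.backbone.get_weights().items()}
    weights.update({f"head/{k}": v for k, v in model.head.get_weights().items()})
    np.savez(prefix + ".npz", **weights)
    s = model.spec
    with open(prefix + ".json", "w") as fh:
        json.dump({"backbone": s.backbone, "n_classes": s.n_classes,
                   "dropout_rate": s.dropout_rate, "input_size": s.input_size,
                   "seed": s.seed}, fh)


def load_classifier(prefix: str) -> Classifier:
    with open(prefix + ".json") as fh:
        d = json.load(fh)
    model = build_classifier(ClassifierSpec(**d))
    with np.load(prefix + ".npz") as data:
        model.backbone.set_weights(
            {k[len("backbone/"):]: v for k, v in data.items()
             if k.startswith("backbone/")})
        model.head.set_weights(
            {k[len("head/"):]: v for k, v in data.items()
             if k.startswith("head/")})
    return model
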