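"""Evaluation protocol: splits, top-k accuracy, PR/AP, grouped confusion.

The protocol holds out 20% of *consumer* items (stratified by class) for
final evaluation; the remaining consumer items form the fourfold CV pool,
and reference items always train.  Ranking metrics: top-k accuracy with
deterministic tie-breaks, micro-averaged precision-recall over pooled
one-vs-rest decisions, and per-class average precision with a lowest-AP
report.  AP uses the step-wise sum ``AP = sum_i (R_i - R_{i-1}) P_i`` over
the threshold sweep (no interpolation smoothing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgument, ValidationError


# ------------------------------------------------------------------ splits --

@dataclass
class SplitPlan:
    holdout_consumer: list
    cv_consumer: list
    reference_always_train: list
    holdout_fraction: float
    seed: int
    folds: dict = field(default_factory=dict)   # item id -> fold index


def assign_folds(labels: np.ndarray, k_folds: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: per class, shuffled round-robin."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k_folds
    return folds


def make_splits(items, holdout_fraction: float = 0.2, k_folds: int = 4,
                seed: int = 0) -> SplitPlan:
    """Hold out a stratified 20% of consumer items; fold the rest.

    ``items`` is a list of dicts with ``id``, ``label`` and ``is_consumer``.
    Reference items never enter the hold-out or any validation fold.  A class
    with fewer than ``k_folds`` consumer CV items keeps its items in training
    folds with a warning (stratification impossible).
    """
    ids = [it["id"] for it in items]
    if len(set(ids)) != len(ids):
        raise InvalidArgument("item ids must be unique")
    consumer = [it for it in items if it["is_consumer"]]
    reference = [it for it in items if not it["is_consumer"]]
    rng = np.random.default_rng(seed)

    n_hold = round(holdout_fraction * len(consumer))
    labels = np.asarray([it["label"] for it in consumer])
    # stratified hold-out: proportional per-class draw, then top up randomly
    holdout_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        take = int(np.floor(holdout_fraction * len(idx)))
        holdout_idx.extend(idx[:take].tolist())
    remaining = [i for i in range(len(consumer)) if i not in set(holdout_idx)]
    rng.shuffle(remaining)
    while len(holdout_idx) < n_hold and remaining:
        holdout_idx.append(remaining.pop())
    holdout_idx = holdout_idx[:n_hold]
    hold_set = set(holdout_idx)
    cv_idx = [i for i in range(len(consumer)) if i not in hold_set]

    cv_labels = labels[cv_idx]
    small = [cls for cls in np.unique(cv_labels)
             if (cv_labels == cls).sum() < k_folds]
    if small:
        warnings.warn(f"classes {small} have fewer than {k_folds} consumer CV "
                      "items; they cannot appear in every validation fold")
    fold_assign = assign_folds(cv_labels, k_folds, seed=seed + 1)
    folds = {consumer[i]["id"]: int(f) for i, f in zip(cv_idx, fold_assign)}
    return SplitPlan(
        holdout_consumer=[consumer[i]["id"] for i in sorted(hold_set)],
        cv_consumer=[consumer[i]["id"] for i in cv_idx],
        reference_always_train=[it["id"] for it in reference],
        holdout_fraction=holdout_fraction, seed=seed, folds=folds)


# ----------------------------------------------------------------- metrics --

def _check_scores(score_matrix, labels):
    s = np.asarray(score_matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.ndim != 2 or len(s) != len(y):
        raise InvalidArgument("score matrix must be n_items x n_classes")
    if y.size and (y.min() < 0 or y.max() >= s.shape[1]):
        raise InvalidArgument("labels out of range")
    return s, y


def topk_accuracy(score_matrix, labels, k: int) -> float:
    """Fraction of items whose true class ranks in the top k.

    Ranking ties break by ascending class index (lower index wins), matching
    the service's deterministic top-k ordering.
    """
    if k < 1:
        raise InvalidArgument("k must be >= 1")
    s, y = _check_scores(score_matrix, labels)
    n, c = s.shape
    k = min(k, c)
    hits = 0
    cols = np.arange(c)
    for i in range(n):
        order = np.lexsort((cols, -s[i]))[:k]
        hits += y[i] in order
    return hits / n


def micro_average_pr(score_matrix, labels):
    """Micro-averaged precision-recall sweep and its average precision.

    All ``n_items x n_classes`` one-vs-rest (score, indicator) pairs are
    pooled; precision and recall are computed at every distinct score
    threshold (descending), and ``AP = sum (R_i - R_{i-1}) * P_i``.
    Returns ``(pr_points, micro_ap)`` with ``pr_points`` a list of
    (recall, precision) tuples.
    """
    s, y = _check_scores(score_matrix, labels)
    if s.shape[1] < 2:
        raise InvalidArgument("micro-averaged PR needs at least 2 classes")
    onehot = np.zeros_like(s, dtype=bool)
    onehot[np.arange(len(y)), y] = True
    return _binary_pr(s.ravel(), onehot.ravel())


def _binary_pr(scores: np.ndarray, positives: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    scores, positives = scores[order], positives[order]
    tp = np.cumsum(positives)
    fp = np.cumsum(~positives)
    n_pos = int(positives.sum())
    if n_pos == 0:
        raise InvalidArgument("no positive example")
    # evaluate only at the last index of each distinct-score run
    distinct = np.flatnonzero(np.diff(scores, append=-np.inf))
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    prev_r = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_r) * precision))
    return list(zip(recall.tolist(), precision.tolist())), ap


def per_class_ap(score_matrix, labels) -> dict[int, float]:
    """One-vs-rest AP per class; classes without positives are omitted."""
    s, y = _check_scores(score_matrix, labels)
    out = {}
    skipped = []
    for cls in range(s.shape[1]):
        pos = y == cls
        if not pos.any():
            skipped.append(cls)
            continue
        _, ap = _binary_pr(s[:, cls], pos)
        out[cls] = ap
    if skipped:
        warnings.warn(f"classes {skipped} have no positives; AP undefined, "
                      "excluded")
    return out


def per_class_ap_report(score_matrix, labels, n_lowest: int) -> list[tuple[int, float]]:
    """The ``n_lowest`` classes in increasing AP order as (class, AP) pairs."""
    aps = per_class_ap(score_matrix, labels)
    ranked = sorted(aps.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) < n_lowest:
        warnings.warn(f"only {len(ranked)} classes have defined AP")
    return ranked[:n_lowest]


def grouped_confusion(predictions, labels, attribute_of_class) -> tuple[np.ndarray, list]:
    """Confusion matrix over a class attribute (e.g. color or shape).

    Rows are the true attribute, columns the predicted one; cell (a, b)
    counts items whose true class has attribute ``a`` and predicted class
    attribute ``b``.  Returns ``(matrix, attribute_categories)`` with
    categories in sorted order.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    missing = [int(c) for c in np.unique(np.concatenate([predictions, labels]))
               if c not in attribute_of_class]
    if missing:
        raise ValidationError(f"classes missing from attribute map: {missing}")
    cats = sorted(set(attribute_of_class.values()))
    cat_idx = {a: i for i, a in enumerate(cats)}
    mat = np.zeros((len(cats), len(cats)), dtype=int)
    for p, t in zip(predictions, labels):
        mat[cat_idx[attribute_of_class[int(t)]],
            cat_idx[attribute_of_class[int(p)]]] += 1
    return mat, cats


def extract_penultimate_features(model, crops) -> np.ndarray:
    """Per-crop activations from just before the first head dense layer.

    For a ResNet50-style classifier this is the 2048-wide post-pooling
    vector (after the head's inference-mode batch-norm; drop-out inactive).
    Deterministic: repeated calls return identical matrices.
    """
    return model.features(np.asarray(crops))


# ------------------------------------------------------------------ report --

@dataclass
class EvalReport:
    top1: float
    top5: float
    per_class_ap: dict
    micro_pr: list
    micro_ap: float
    confusion_by_color: list
    confusion_by_shape: list
    color_categories: list
    shape_categories: list
    lowest_ap_classes: list

    def to_json(self):
        return {
            "top1": self.top1, "top5": self.top5,
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "micro_pr": self.micro_pr, "micro_ap": self.micro_ap,
            "confusion_by_color": self.confusion_by_color,
            "confusion_by_shape": self.confusion_by_shape,
            "color_categories": self.color_categories,
            "shape_categories": self.shape_categories,
            "lowest_ap_classes": self.lowest_ap_classes,
        }


def evaluate_scores(score_matrix, labels, class_colors=None, class_shapes=None,
                    n_lowest: int = 10) -> EvalReport:
    """Full evaluation report from a score matrix and true labels."""
    s, y = _check_scores(score_matrix, labels)
    preds = s.argmax(axis=1)
    pr, micro_ap = micro_average_pr(s, y)
    aps = per_class_ap(s, y)
    colors = class_colors or {}
    shapes = class_shapes or {}
    if colors:
        cm_color, color_cats = grouped_confusion(preds, y, colors)
    else:
        cm_color, color_cats = np.zeros((0, 0), dtype=int), []
    if shapes:
        cm_shape, shape_cats = grouped_confusion(preds, y, shapes)
    else:
        cm_shape, shape_cats = np.zeros((0, 0), dtype=int), []
    return EvalReport(
        top1=topk_accuracy(s, y, 1), top5=topk_accuracy(s, y, 5),
        per_class_ap=aps, micro_pr=[list(p) for p in pr], micro_ap=micro_ap,
        confusion_by_color=cm_color.tolist(), confusion_by_shape=cm_shape.tolist(),
        color_categories=color_cats, shape_categories=shape_cats,
        lowest_ap_classes=[list(t) for t in
                           per_class_ap_report(s, y, min(n_lowest, len(aps)))])
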