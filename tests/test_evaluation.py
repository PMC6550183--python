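"""Splits, ranking metrics and their brute-force / sklearn oracles."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from pillpipe.errors import InvalidArgument, ValidationError
from pillpipe.evaluation import (EvalReport, assign_folds, evaluate_scores,
                                 extract_penultimate_features,
                                 grouped_confusion, make_splits,
                                 micro_average_pr, per_class_ap,
                                 per_class_ap_report, topk_accuracy)


def topk_oracle(scores, labels, k):
    """Independent top-k check: rank = #(strictly greater) + #(ties, lower idx)."""
    hits = 0
    for row, y in zip(scores, labels):
        rank = sum(1 for c, s in enumerate(row)
                   if s > row[y] or (s == row[y] and c < y))
        hits += rank < k
    return hits / len(labels)


class TestMakeSplits:
    def _items(self, n_consumer=100, n_reference=30, n_classes=5):
        items = [{"id": f"c{i}", "label": i % n_classes, "is_consumer": True}
                 for i in range(n_consumer)]
        items += [{"id": f"r{i}", "label": i % n_classes, "is_consumer": False}
                  for i in range(n_reference)]
        return items

    def test_holdout_is_twenty_percent_of_consumer_items(self):
        plan = make_splits(self._items(), seed=0)
        assert len(plan.holdout_consumer) == 20
        assert len(plan.cv_consumer) == 80

    def test_reference_items_never_in_holdout_or_folds(self):
        plan = make_splits(self._items(), seed=1)
        held = set(plan.holdout_consumer) | set(plan.folds)
        assert all(rid.startswith("c") for rid in held)
        assert len(plan.reference_always_train) == 30

    def test_partitions_are_disjoint_and_exhaustive(self):
        plan = make_splits(self._items(), seed=2)
        hold, cv = set(plan.holdout_consumer), set(plan.cv_consumer)
        assert hold.isdisjoint(cv)
        assert hold | cv == {f"c{i}" for i in range(100)}
        assert set(plan.folds) == cv
        assert set(plan.folds.values()) == {0, 1, 2, 3}

    def test_same_seed_reproduces_plan(self):
        a = make_splits(self._items(), seed=3)
        b = make_splits(self._items(), seed=3)
        assert a.holdout_consumer == b.holdout_consumer
        assert a.folds == b.folds

    def test_stratification_keeps_all_classes_evaluable(self):
        plan = make_splits(self._items(200, 0, 10), seed=4)
        items = {it["id"]: it for it in self._items(200, 0, 10)}
        hold_labels = {items[i]["label"] for i in plan.holdout_consumer}
        assert hold_labels == set(range(10))

    def test_tiny_class_warns(self):
        items = self._items(40, 0, 4)
        items.append({"id": "solo", "label": 99, "is_consumer": True})
        with pytest.warns(UserWarning):
            make_splits(items, seed=5)

    def test_fold_assignment_is_stratified(self):
        labels = np.repeat(np.arange(5), 8)
        folds = assign_folds(labels, 4, seed=0)
        for cls in range(5):
            counts = np.bincount(folds[labels == cls], minlength=4)
            assert counts.max() - counts.min() <= 1


class TestTopkAccuracy:
    def test_hand_ranked_example(self):
        # true class ranks 1st, 3rd and 6th in these three rows
        scores = np.array([
            [0.9, 0.05, 0.02, 0.01, 0.01, 0.01],
            [0.5, 0.3, 0.1, 0.05, 0.03, 0.02],
            [0.3, 0.25, 0.2, 0.12, 0.08, 0.05],
        ])
        labels = np.array([0, 2, 5])
        assert topk_accuracy(scores, labels, 1) == pytest.approx(1 / 3)
        assert topk_accuracy(scores, labels, 5) == pytest.approx(2 / 3)

    def test_k_equal_to_n_classes_is_one(self):
        rng = np.random.default_rng(0)
        s = rng.random((10, 6))
        y = rng.integers(0, 6, 10)
        assert topk_accuracy(s, y, 6) == 1.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(1)
        s = rng.random((30, 8))
        y = rng.integers(0, 8, 30)
        accs = [topk_accuracy(s, y, k) for k in range(1, 9)]
        assert accs == sorted(accs)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_rank_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, c = int(rng.integers(3, 20)), int(rng.integers(2, 7))
        s = np.round(rng.random((n, c)), 2)  # rounded scores force ties
        y = rng.integers(0, c, n)
        for k in (1, 2, 5):
            assert topk_accuracy(s, y, k) == pytest.approx(topk_oracle(s, y, k))

    def test_invalid_k_rejected(self):
        with pytest.raises(InvalidArgument):
            topk_accuracy(np.eye(3), [0, 1, 2], 0)


def ap_threshold_sweep_oracle(scores, positives):
    """Brute force: evaluate P/R at every distinct threshold, sum steps."""
    pairs = sorted(zip(scores, positives), key=lambda t: -t[0])
    n_pos = sum(p for _, p in pairs)
    thresholds = sorted({s for s, _ in pairs}, reverse=True)
    ap, prev_r = 0.0, 0.0
    for th in thresholds:
        sel = [(s, p) for s, p in pairs if s >= th]
        tp = sum(p for _, p in sel)
        prec = tp / len(sel)
        rec = tp / n_pos
        ap += (rec - prev_r) * prec
        prev_r = rec
    return ap


class TestMicroAveragePR:
    def test_perfect_scores_give_ap_one(self):
        y = np.array([0, 1, 2, 1])
        s = np.zeros((4, 3))
        s[np.arange(4), y] = 1.0
        _, ap = micro_average_pr(s, y)
        assert ap == pytest.approx(1.0)

    def test_hand_example_matches_threshold_sweep_oracle(self):
        s = np.array([[0.7, 0.2, 0.1],
                      [0.1, 0.6, 0.3],
                      [0.4, 0.4, 0.2],
                      [0.2, 0.3, 0.5]])
        y = np.array([0, 2, 1, 2])
        onehot = np.zeros_like(s, bool)
        onehot[np.arange(4), y] = True
        expected = ap_threshold_sweep_oracle(s.ravel().tolist(),
                                             onehot.ravel().tolist())
        _, ap = micro_average_pr(s, y)
        assert ap == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_sklearn_micro_average(self, seed):
        rng = np.random.default_rng(seed)
        n, c = int(rng.integers(4, 20)), int(rng.integers(2, 6))
        s = rng.random((n, c))
        y = rng.integers(0, c, n)
        onehot = np.zeros_like(s)
        onehot[np.arange(n), y] = 1
        _, ap = micro_average_pr(s, y)
        assert ap == pytest.approx(
            average_precision_score(onehot.ravel(), s.ravel()))

    def test_bounded_for_random_inputs(self):
        rng = np.random.default_rng(9)
        s = rng.random((50, 4))
        y = rng.integers(0, 4, 50)
        _, ap = micro_average_pr(s, y)
        assert 0.0 <= ap <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgument):
            micro_average_pr(np.ones((4, 1)), np.zeros(4, int))


class TestPerClassAP:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_per_class(self, seed):
        rng = np.random.default_rng(seed)
        n, c = 20, 4
        s = rng.random((n, c))
        y = rng.integers(0, c, n)
        aps = per_class_ap(s, y)
        for cls, ap in aps.items():
            assert ap == pytest.approx(
                average_precision_score((y == cls).astype(int), s[:, cls]))

    def test_always_confident_class_not_in_lowest_report(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 0.5, (12, 3))
        y = np.array([0, 1, 2] * 4)
        s[y == 0, 0] = 1.0  # class 0 perfectly ranked
        report = per_class_ap_report(s, y, 2)
        classes = [cls for cls, _ in report]
        assert 0 not in classes
        assert len(report) == 2
        assert report[0][1] <= report[1][1]

    def test_engineered_worst_class_ranks_lowest(self):
        # class 2's positives always score below class 0 impostors
        s = np.array([[0.9, 0.0, 0.3], [0.8, 0.1, 0.2],
                      [0.1, 0.9, 0.35], [0.0, 0.8, 0.25],
                      [0.7, 0.1, 0.1], [0.6, 0.2, 0.15]])
        y = np.array([0, 0, 1, 1, 2, 2])
        report = per_class_ap_report(s, y, 1)
        assert report[0][0] == 2

    def test_zero_positive_class_excluded_with_warning(self):
        s = np.random.default_rng(0).random((6, 3))
        y = np.array([0, 0, 1, 1, 0, 1])  # class 2 never appears
        with pytest.warns(UserWarning):
            aps = per_class_ap(s, y)
        assert 2 not in aps


class TestGroupedConfusion:
    ATTR = {0: "WHITE", 1: "WHITE", 2: "RED", 3: "BLUE"}

    def test_all_correct_is_diagonal(self):
        y = np.array([0, 1, 2, 3, 0, 2])
        mat, cats = grouped_confusion(y, y, self.ATTR)
        assert cats == ["BLUE", "RED", "WHITE"]
        assert np.trace(mat) == 6 and mat.sum() == 6

    def test_total_equals_item_count(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, 50)
        p = rng.integers(0, 4, 50)
        mat, _ = grouped_confusion(p, y, self.ATTR)
        assert mat.sum() == 50

    def test_hand_counted_mistakes(self):
        y = np.array([0, 1, 2, 2, 3, 3])
        p = np.array([0, 2, 2, 0, 3, 2])  # WHITE->RED and BLUE->RED mistakes
        mat, cats = grouped_confusion(p, y, self.ATTR)
        i = {c: k for k, c in enumerate(cats)}
        assert mat[i["WHITE"], i["RED"]] == 1
        assert mat[i["BLUE"], i["RED"]] == 1
        assert mat[i["RED"], i["WHITE"]] == 1

    def test_top1_from_identity_attribute_confusion(self):
        rng = np.random.default_rng(5)
        s = rng.random((40, 4))
        y = rng.integers(0, 4, 40)
        preds = s.argmax(axis=1)
        mat, _ = grouped_confusion(preds, y, {c: str(c) for c in range(4)})
        assert np.trace(mat) / mat.sum() == pytest.approx(
            topk_accuracy(s, y, 1))

    def test_missing_class_in_attribute_map_rejected(self):
        with pytest.raises(ValidationError):
            grouped_confusion([0, 5], [0, 5], {0: "WHITE"})


class TestPenultimateFeatures:
    def test_feature_width_matches_backbone_pooled_width(self):
        from pillpipe.classifier import ClassifierSpec, build_classifier
        resnet = build_classifier(ClassifierSpec(backbone="RESNET50",
                                                 n_classes=10))
        assert resnet.feature_width == 2048
        small = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=10))
        crops = np.random.default_rng(0).integers(
            0, 256, (3, 224, 224, 3)).astype(np.uint8)
        feats = extract_penultimate_features(small, crops)
        assert feats.shape == (3, small.feature_width)

    def test_repeated_extraction_is_identical(self):
        from pillpipe.classifier import ClassifierSpec, build_classifier
        model = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=5, dropout_rate=0.5))
        crops = np.random.default_rng(1).integers(
            0, 256, (2, 224, 224, 3)).astype(np.uint8)
        a = extract_penultimate_features(model, crops)
        b = extract_penultimate_features(model, crops)
        assert np.array_equal(a, b)


class TestEvaluateScores:
    def test_report_invariants(self):
        rng = np.random.default_rng(2)
        s = rng.random((30, 5))
        y = rng.integers(0, 5, 30)
        rep = evaluate_scores(s, y, class_colors={c: "WHITE" for c in range(5)},
                              class_shapes={c: ["ROUND", "OVAL"][c % 2]
                                            for c in range(5)})
        assert 0 <= rep.top1 <= rep.top5 <= 1
        assert 0 <= rep.micro_ap <= 1
        assert np.asarray(rep.confusion_by_shape).sum() == 30
        json_blob = rep.to_json()
        assert set(json_blob) >= {"top1", "top5", "micro_ap", "micro_pr"}
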