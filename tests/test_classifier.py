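"""Label merging, head surgery, parameter accounting, search and top-k."""

import numpy as np
import pytest

from pillpipe.classifier import (ClassifierSpec, HyperParams, NDCLabelMap,
                                 build_classifier, build_ndc_label_map,
                                 count_parameters, expand_grid, finetune,
                                 grid_search_cv, predict_topk)
from pillpipe.errors import InvalidArgument, ValidationError
from pillpipe.nn.layers import BatchNorm, Dense, Dropout, ReLU
from pillpipe.nn.optim import TrainSchedule


class TestNDCLabelMap:
    def test_categories_sharing_an_ndc_merge(self):
        rows = [("c1", "111"), ("c2", "222"), ("c3", "111"),
                ("c4", "333"), ("c5", "444")]
        lm = build_ndc_label_map(rows)
        assert lm.n_classes == 4
        assert lm.category_to_ndc["c1"] == lm.category_to_ndc["c3"] == "111"

    def test_distinct_ndcs_keep_distinct_classes(self):
        lm = build_ndc_label_map([(f"c{i}", f"ndc{i}") for i in range(7)])
        assert lm.n_classes == 7

    def test_missing_ndc_lists_offenders(self):
        with pytest.raises(ValidationError) as exc:
            build_ndc_label_map([("a", "1"), ("b", ""), ("c", None)])
        assert "b" in str(exc.value) and "c" in str(exc.value)

    def test_index_roundtrip_is_identity(self):
        lm = build_ndc_label_map([(f"c{i}", f"{i:05d}") for i in range(20)])
        for ndc, idx in lm.ndc_to_index.items():
            assert lm.index_to_ndc(idx) == ndc

    def test_indices_assigned_by_sorted_ndc(self):
        lm = build_ndc_label_map([("a", "zz"), ("b", "aa"), ("c", "mm")])
        assert lm.ndc_to_index == {"aa": 0, "mm": 1, "zz": 2}

    def test_challenge_scale_merge(self):
        # synthetic stand-in for the challenge metadata: 1000 appearance
        # categories over 924 distinct NDC codes (some pills appear in
        # several appearance variants of the same product)
        n_categories, n_products = 1000, 924
        rows = [(f"cat{i:04d}", f"{i % n_products:05d}-{(i % n_products) % 997:03d}")
                for i in range(n_categories)]
        expected = len({ndc for _, ndc in rows})
        lm = build_ndc_label_map(rows)
        assert lm.n_classes == expected == n_products

    def test_json_roundtrip(self, tmp_path):
        lm = build_ndc_label_map([("a", "1"), ("b", "2")])
        lm.to_json(str(tmp_path / "lm.json"))
        back = NDCLabelMap.from_json(str(tmp_path / "lm.json"))
        assert back.ndc_to_index == lm.ndc_to_index


PUBLISHED_COUNTS = {
    "RESNET50": 26_347_576,   # 26.35 M
    "MOBILENET": 5_038_456,   # 5.04 M
    "SQUEEZENET": 2_056_952,  # 2.06 M
}


class TestBuildClassifier:
    @pytest.mark.parametrize("backbone,expected", PUBLISHED_COUNTS.items())
    def test_total_parameter_counts_match_published_architecture(self, backbone,
                                                                 expected):
        model = build_classifier(ClassifierSpec(backbone=backbone, n_classes=924))
        assert count_parameters(model) == expected

    def test_head_is_two_bn_dropout_dense_blocks(self):
        model = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=10, dropout_rate=0.4))
        kinds = [type(l).__name__ for l in model.head.layers]
        assert kinds == ["BatchNorm", "Dropout", "Dense", "ReLU",
                         "BatchNorm", "Dropout", "Dense"]
        drops = [l for l in model.head.layers if isinstance(l, Dropout)]
        assert len(drops) == 2 and all(d.rate == 0.4 for d in drops)
        denses = [l for l in model.head.layers if isinstance(l, Dense)]
        assert denses[0].w.value.shape[1] == 10
        assert denses[1].w.value.shape == (10, 10)

    def test_softmax_outputs_sum_to_one(self):
        model = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=7))
        crops = np.random.default_rng(0).integers(0, 256, (3, 224, 224, 3))
        probs = model.predict_proba(crops.astype(np.uint8))
        assert probs.shape == (3, 7)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(InvalidArgument):
            build_classifier(ClassifierSpec(backbone="VGG99", n_classes=5))

    def test_pretrained_without_weights_rejected(self):
        with pytest.raises(InvalidArgument):
            build_classifier(ClassifierSpec(backbone="SMALL_TEST", n_classes=5,
                                            pretrained=True))


class TestCountParameters:
    def test_dense_with_bias(self):
        assert count_parameters(Dense(10, 5)) == 55

    def test_batchnorm_counts_statistics(self):
        assert BatchNorm(64).param_count == 256

    def test_sequential_additivity(self):
        from pillpipe.nn import Sequential
        a, b = Dense(4, 3), Dense(3, 2)
        assert (Sequential([a, b]).param_count
                == a.param_count + b.param_count)


class TestFinetune:
    def test_out_of_range_label_rejected(self):
        model = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=3))
        x = np.zeros((4, 224, 224, 3), np.uint8)
        with pytest.raises(ValidationError):
            finetune(model, (x, np.array([0, 1, 2, 3])), (x, np.zeros(4, int)),
                     HyperParams(), TrainSchedule(max_epochs=1))

    def test_lr_trace_changes_only_by_plateau_factor(self, trained_classifier):
        lrs = trained_classifier.history.trace("lr")
        for prev, cur in zip(lrs, lrs[1:]):
            assert cur == prev or cur == pytest.approx(prev * 0.2)

    def test_memorizes_small_training_set(self):
        # overfit sanity check on the training loop: 10 classes x 20 clean
        # crops, no drop-out, constant LR (plateau patience beyond the run)
        from pillpipe.synthetic_data import generate_classification_set
        data = generate_classification_set(10, 20, seed=0, augment=False)
        x, y = data["crops"], data["labels"]
        model = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=10, dropout_rate=0.0,
                                                seed=1))
        sched = TrainSchedule(initial_lr=1e-3, max_epochs=100, batch_size=16,
                              plateau_patience=100, early_stop_patience=100)
        model, hist = finetune(model, (x, y), (x, y),
                               HyperParams(initial_lr=1e-3), sched, seed=1)
        probs = model.predict_proba(x)
        assert (probs.argmax(axis=1) == y).mean() >= 0.99


class TestGridSearchCV:
    def _pool(self, n_consumer=40, n_reference=10, n_classes=4):
        pool = [{"id": f"c{i}", "label": i % n_classes, "is_consumer": True}
                for i in range(n_consumer)]
        pool += [{"id": f"r{i}", "label": i % n_classes, "is_consumer": False}
                 for i in range(n_reference)]
        return pool

    def test_enumerates_six_configs_and_24_fold_fits(self):
        calls = []

        def trainer(hp, train_items, val_items):
            calls.append((hp.dropout_rate, hp.initial_lr))
            return {"top1": 0.5, "top5": 0.9}

        best, table = grid_search_cv(trainer, self._pool(), k_folds=4)
        assert len(table) == 6
        assert len(calls) == 24
        assert all(len(row["fold_scores"]) == 4 for row in table)
        grid = {(hp.dropout_rate, hp.initial_lr) for hp in expand_grid()}
        assert grid == {(d, lr) for d in (0.2, 0.4)
                        for lr in (5e-5, 1e-4, 5e-4)}

    def test_returns_argmax_of_mock_scores(self):
        scores = {(0.2, 5e-5): 0.1, (0.2, 1e-4): 0.9, (0.2, 5e-4): 0.3,
                  (0.4, 5e-5): 0.2, (0.4, 1e-4): 0.4, (0.4, 5e-4): 0.5}

        def trainer(hp, train_items, val_items):
            s = scores[(hp.dropout_rate, hp.initial_lr)]
            return {"top1": s / 2, "top5": s}

        best, _ = grid_search_cv(trainer, self._pool())
        assert (best.dropout_rate, best.initial_lr) == (0.2, 1e-4)

    def test_tie_breaks_prefer_higher_top1_then_lower_lr(self):
        def trainer(hp, train_items, val_items):
            top1 = 0.6 if hp.initial_lr <= 1e-4 else 0.4
            return {"top1": top1, "top5": 0.9}

        best, _ = grid_search_cv(trainer, self._pool())
        assert best.initial_lr == 5e-5  # equal top5/top1 -> lowest lr wins

    def test_reference_items_join_every_training_split(self):
        seen_refs = []

        def trainer(hp, train_items, val_items):
            seen_refs.append(all(not it["is_consumer"] or True for it in train_items))
            assert all(it["is_consumer"] for it in val_items)
            n_ref = sum(not it["is_consumer"] for it in train_items)
            assert n_ref == 10
            return {"top1": 0.5, "top5": 0.9}

        grid_search_cv(trainer, self._pool(),
                       grid={"dropout_rate": (0.2,), "initial_lr": (1e-4,)})

    def test_class_missing_from_training_split_rejected(self):
        pool = [{"id": "c0", "label": 0, "is_consumer": True},
                {"id": "c1", "label": 1, "is_consumer": True}]
        with pytest.raises(ValidationError):
            grid_search_cv(lambda *a: {"top1": 0, "top5": 0}, pool, k_folds=2)


class TestPredictTopk:
    @pytest.fixture(scope="class")
    def model_and_map(self):
        model = build_classifier(ClassifierSpec(backbone="SMALL_TEST",
                                                n_classes=8, seed=2))
        ndcs = [f"{i:05d}-001" for i in range(8)]
        lm = NDCLabelMap(category_to_ndc={str(i): n for i, n in enumerate(ndcs)},
                         ndc_to_index={n: i for i, n in enumerate(ndcs)})
        return model, lm

    def test_returns_k_distinct_sorted_entries(self, model_and_map):
        model, lm = model_and_map
        crop = np.random.default_rng(3).integers(0, 256, (224, 224, 3)).astype(np.uint8)
        pred = predict_topk(model, crop, lm, k=5)
        assert len(pred) == 5
        confs = [c for _, c in pred]
        assert confs == sorted(confs, reverse=True)
        assert len({n for n, _ in pred}) == 5

    def test_top1_is_prefix_of_top5(self, model_and_map):
        model, lm = model_and_map
        crop = np.random.default_rng(4).integers(0, 256, (224, 224, 3)).astype(np.uint8)
        assert predict_topk(model, crop, lm, k=1).entries[0] == \
            predict_topk(model, crop, lm, k=5).entries[0]

    def test_k_above_n_classes_clamped_with_warning(self, model_and_map):
        model, lm = model_and_map
        crop = np.zeros((224, 224, 3), np.uint8)
        with pytest.warns(UserWarning):
            pred = predict_topk(model, crop, lm, k=20)
        assert len(pred) == 8
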