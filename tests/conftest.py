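"""Shared fixtures: synthetic datasets and (expensively) trained models.

The trained detector and classifier are session-scoped so the end-to-end,
service and acceptance tests share one training run each.
"""

import numpy as np
import pytest

from pillpipe.classifier import (ClassifierSpec, HyperParams, NDCLabelMap,
                                 build_classifier, finetune)
from pillpipe.localization import DetectorSpec, build_fcn, train_detector
from pillpipe.nn.optim import TrainSchedule
from pillpipe.synthetic_data import (BACKGROUND_KINDS, SceneParams,
                                     compose_scene, generate_classification_set,
                                     make_background, make_default_catalog)

DET_CANVAS = (96, 128)
N_DET_TRAIN = 200
N_DET_VAL = 40


def make_scene_arrays(n, seed=0, canvas=DET_CANVAS):
    """Consumer-style scenes at reduced resolution, with union masks."""
    params = SceneParams().scaled_down(canvas)
    pool = make_default_catalog(base_size=48, seed=0)
    imgs, masks, scenes = [], [], []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        kind = BACKGROUND_KINDS[int(rng.integers(len(BACKGROUND_KINDS)))]
        bg = make_background(kind, params.canvas, rng)
        sc = compose_scene(pool, bg, params, rng)
        imgs.append(sc.image)
        masks.append(sc.union_mask)
        scenes.append(sc)
    return np.stack(imgs), np.stack(masks), scenes


@pytest.fixture(scope="session")
def detector_data():
    imgs, masks, scenes = make_scene_arrays(N_DET_TRAIN + N_DET_VAL, seed=0)
    return {"train": (imgs[:N_DET_TRAIN], masks[:N_DET_TRAIN]),
            "val": (imgs[N_DET_TRAIN:], masks[N_DET_TRAIN:]),
            "val_scenes": scenes[N_DET_TRAIN:]}


@pytest.fixture(scope="session")
def trained_detector(detector_data):
    det = build_fcn(DetectorSpec(input_shape=(*DET_CANVAS, 3),
                                 backbone="small", seed=0))
    schedule = TrainSchedule(initial_lr=1e-3, max_epochs=35, batch_size=4,
                             plateau_patience=3, early_stop_patience=12)
    det, history = train_detector(det, detector_data["train"],
                                  detector_data["val"], schedule, seed=0)
    det.history = history
    return det


@pytest.fixture(scope="session")
def classification_data():
    return generate_classification_set(n_classes=10, per_class=100, seed=0)


@pytest.fixture(scope="session")
def classification_splits(classification_data):
    n = len(classification_data["labels"])
    rng = np.random.default_rng(1)
    order = rng.permutation(n)
    return {"train": order[:int(0.7 * n)],
            "val": order[int(0.7 * n):int(0.8 * n)],
            "holdout": order[int(0.8 * n):]}


@pytest.fixture(scope="session")
def trained_classifier(classification_data, classification_splits):
    data, splits = classification_data, classification_splits
    tr, va = splits["train"], splits["val"]
    model = build_classifier(ClassifierSpec(backbone="SMALL_TEST", n_classes=10,
                                            dropout_rate=0.2, seed=0))
    schedule = TrainSchedule(initial_lr=1e-3, max_epochs=40, batch_size=32,
                             plateau_patience=3, early_stop_patience=10)
    model, history = finetune(
        model, (data["crops"][tr], data["labels"][tr]),
        (data["crops"][va], data["labels"][va]),
        HyperParams(dropout_rate=0.2, initial_lr=1e-3), schedule, seed=0)
    model.history = history
    return model


@pytest.fixture(scope="session")
def label_map(classification_data):
    ndcs = classification_data["class_ndcs"]
    return NDCLabelMap(
        category_to_ndc={str(i): ndc for i, ndc in enumerate(ndcs)},
        ndc_to_index={ndc: i for i, ndc in enumerate(ndcs)})
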