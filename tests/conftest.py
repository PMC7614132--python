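import numpy as np
import pytest

import organoquant as oq
from organoquant.io import TrainConfig

# The classifier benchmark: 1,000 balanced training crops (seed 3) and 200
# fresh held-out crops (seed 11). Session-scoped so the CNN trains once for
# the whole suite.


@pytest.fixture(scope="session")
def crop_benchmark():
    train = oq.generate_crop_dataset(1000, seed=3)
    test = oq.generate_crop_dataset(200, seed=11)
    return train, test


@pytest.fixture(scope="session")
def cnn_model(crop_benchmark):
    (crops, labels), _ = crop_benchmark
    return oq.train_classifier(list(zip(crops, labels)), TrainConfig(kind="cnn"), seed=3)


@pytest.fixture(scope="session")
def fallback_model(crop_benchmark):
    (crops, labels), _ = crop_benchmark
    return oq.train_classifier(list(zip(crops, labels)),
                               TrainConfig(kind="shape_features"), seed=3)


def holdout_accuracy(model, test_set):
    crops, labels = test_set
    probs = model.predict_proba(crops)
    pred = [model.class_map[i] for i in probs.argmax(axis=1)]
    return float(np.mean([p == t for p, t in zip(pred, labels)]))


@pytest.fixture(scope="session")
def small_scene():
    """One seeded brightfield scene with 3 spheroids and 2 budding organoids."""
    return oq.generate_brightfield_scene(3, 2, (512, 512), seed=7)
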