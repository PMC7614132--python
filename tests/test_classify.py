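import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

import organoquant as oq
from organoquant.io import CropConfig, Image2D, LabelMask, OrganoidRecord, TrainConfig

from conftest import holdout_accuracy


def _disk_scene(radius=15, center=(32, 32), shape=(64, 64), gray=80):
    labels = np.zeros(shape, np.int32)
    rr, cc = draw_disk(center, radius, shape=shape)
    labels[rr, cc] = 1
    img = np.full(shape, 200, np.uint8)
    img[rr, cc] = gray
    return Image2D(img), LabelMask(labels)


def test_crop_is_centered_and_deterministic():
    image, mask = _disk_scene()
    crops = oq.make_crops(image, mask, CropConfig(side=64))
    assert len(crops) == 1
    crop = crops[0]
    nz = np.argwhere(crop.pixels > 0.02)
    center = nz.mean(axis=0)
    assert np.all(np.abs(center - (crop.pixels.shape[0] - 1) / 2) <= 1.0)
    again = oq.make_crops(image, mask, CropConfig(side=64))[0]
    np.testing.assert_array_equal(crop.pixels, again.pixels)


def test_tiny_object_flagged_unclassifiable():
    image, mask = _disk_scene(radius=2)
    crops = oq.make_crops(image, mask, CropConfig(min_crop_pixels=50))
    assert crops[0].unclassifiable


class _StubModel:
    """Fixed-probability model for decision-rule tests."""

    kind = "shape_features"
    class_map = ("spheroid", "budding")

    def __init__(self, p_spheroid):
        self.p = p_spheroid

    def predict_proba(self, crops):
        return np.array([[self.p, 1 - self.p]] * len(crops))


def _records_for(mask):
    return [OrganoidRecord(int(i), 10.0, 50.0) for i in mask.object_ids]


def test_classification_decision_rule():
    image, mask = _disk_scene()
    crops = oq.make_crops(image, mask)
    records = _records_for(mask)
    confident = oq.classify_organoids(crops, _StubModel(0.95), records, 0.05)
    assert confident[0].class_label == "spheroid"
    assert confident[0].confidence == pytest.approx(0.95)
    # |p - 0.5| < margin -> unclassified and queued for review
    marginal = oq.classify_organoids(crops, _StubModel(0.51), records, 0.05)
    assert marginal[0].class_label == "unclassified"
    assert math.isnan(marginal[0].confidence)
    # the budding side of the rule
    budding = oq.classify_organoids(crops, _StubModel(0.05), records, 0.05)
    assert budding[0].class_label == "budding"


def test_unclassifiable_crop_never_gets_a_class():
    image, mask = _disk_scene(radius=2)
    crops = oq.make_crops(image, mask, CropConfig(min_crop_pixels=50))
    out = oq.classify_organoids(crops, _StubModel(0.99), _records_for(mask), 0.0)
    assert out[0].class_label == "unclassified"


def test_training_contracts():
    crops, labels = oq.generate_crop_dataset(20, seed=0)
    with pytest.raises(ValueError):
        oq.train_classifier([], TrainConfig(kind="shape_features"))
    single = [(c, "spheroid") for c in crops]
    with pytest.raises(ValueError, match="both classes"):
        oq.train_classifier(single, TrainConfig(kind="shape_features"))


def test_training_is_deterministic():
    crops, labels = oq.generate_crop_dataset(60, seed=0)
    pairs = list(zip(crops, labels))
    cfg = TrainConfig(kind="cnn", epochs=2)
    m1 = oq.train_classifier(pairs, cfg, seed=5)
    m2 = oq.train_classifier(pairs, cfg, seed=5)
    assert (m1.metadata["validation_accuracy"]
            == m2.metadata["validation_accuracy"])
    np.testing.assert_array_equal(m1.cnn.w_fc, m2.cnn.w_fc)


def test_cnn_beats_benchmark(cnn_model, crop_benchmark):
    _, test_set = crop_benchmark
    assert holdout_accuracy(cnn_model, test_set) >= 0.90


def test_fallback_beats_benchmark(fallback_model, crop_benchmark):
    _, test_set = crop_benchmark
    assert holdout_accuracy(fallback_model, test_set) >= 0.85


def test_cnn_and_fallback_agree_on_most_crops(cnn_model, fallback_model, crop_benchmark):
    _, (crops, _) = crop_benchmark
    cnn_pred = cnn_model.predict_proba(crops).argmax(axis=1)
    fb_pred = fallback_model.predict_proba(crops).argmax(axis=1)
    assert np.mean(cnn_pred == fb_pred) >= 0.80


def test_end_to_end_scene_classification(cnn_model, small_scene):
    """Segment a full synthetic scene and check class assignments against
    ground truth for at least 90% of objects."""
    image, gt = small_scene
    mask = oq.segment_brightfield(image)
    records = oq.extract_features(mask, image)
    crops = oq.make_crops(image, mask)
    out = oq.classify_organoids(crops, cnn_model, records, decision_margin=0.0)
    matches, _, _ = oq.match_objects(mask, gt.true_mask)
    truth = {pid: gt.true_classes[tid] for pid, tid, _ in matches}
    hits = [r.class_label == truth[r.organoid_id] for r in out if r.organoid_id in truth]
    assert np.mean(hits) >= 0.9


# --------------------------------------------------------------------------
# manual-correction cycle
# --------------------------------------------------------------------------


def _classified_records():
    return [
        OrganoidRecord(1, 10.0, 50.0, "spheroid", 0.9, image_id="img0"),
        OrganoidRecord(2, 12.0, 60.0, "budding", 0.8, image_id="img0"),
        OrganoidRecord(3, 14.0, 70.0, "spheroid", 0.7, image_id="img0"),
        OrganoidRecord(4, 16.0, 80.0, "budding", 0.95, image_id="img0"),
    ]


def test_export_apply_round_trip_is_identity(tmp_path):
    records = _classified_records()
    sheet_path = tmp_path / "sheet.csv"
    oq.export_review_sheet(records, sheet_path)
    assert oq.apply_corrections(records, sheet_path) == records


def test_single_correction_is_local():
    records = _classified_records()
    sheet = oq.export_review_sheet(records)
    sheet.loc[sheet.organoid_id == 1, "corrected_class"] = "budding"
    out = oq.apply_corrections(records, sheet)
    assert out[0].class_label == "budding"
    assert out[0].previous_label == "spheroid"
    assert out[0].review_status == "corrected"
    assert out[1:] == records[1:]
    # summary percentages follow the correction
    for r in out:
        r.treatment = "control"
    summary = oq.summarize_treatment(out)[0]
    assert summary.percent_budding == pytest.approx(75.0)


def test_apply_corrections_is_idempotent():
    records = _classified_records()
    sheet = oq.export_review_sheet(records)
    sheet.loc[sheet.organoid_id == 2, "corrected_class"] = "spheroid"
    sheet.loc[sheet.organoid_id == 3, "reject"] = "1"
    once = oq.apply_corrections(records, sheet)
    twice = oq.apply_corrections(once, sheet)
    assert once == twice
    assert once[2].review_status == "rejected"


def test_corrections_validate_ids_and_classes():
    records = _classified_records()
    sheet = oq.export_review_sheet(records)
    bad_id = sheet.copy()
    bad_id.loc[0, "organoid_id"] = 99
    with pytest.raises(ValueError, match="unknown organoid"):
        oq.apply_corrections(records, bad_id)
    bad_class = sheet.copy()
    bad_class.loc[0, "corrected_class"] = "amorphous"
    with pytest.raises(ValueError, match="invalid corrected_class"):
        oq.apply_corrections(records, bad_class)


def test_concordance_metrics():
    records = _classified_records()
    assert oq.concordance(records, records)["agreement"] == 1.0
    sheet = oq.export_review_sheet(records)
    sheet.loc[sheet.organoid_id == 1, "corrected_class"] = "budding"
    corrected = oq.apply_corrections(records, sheet)
    res = oq.concordance(records, corrected)
    assert res["agreement"] == pytest.approx(0.75)
    # confusion marginals equal per-class counts of the automatic labels
    table = res["confusion"]
    assert table.sum(axis=1).to_dict() == {"budding": 2, "spheroid": 2}
    with pytest.raises(ValueError, match="same organoids"):
        oq.concordance(records, records[:2])
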