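import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

import organoquant as oq
from organoquant.io import Image2D, LabelMask, OrganoidRecord, SpotConfig
from organoquant.quant import RoiSet


def test_positive_pixel_fraction_definition():
    px = np.zeros((10, 10), np.uint8)
    px[:5] = 50
    px[5:] = 150
    channel = Image2D(px)
    region = np.ones((10, 10), bool)
    assert oq.positive_pixel_fraction(channel, region, 100) == 0.5
    assert oq.positive_pixel_fraction(channel, region, 150) == 0.0  # strict >
    assert oq.positive_pixel_fraction(channel, region, 255) == 0.0
    with pytest.raises(ValueError, match="empty region"):
        oq.positive_pixel_fraction(channel, np.zeros((10, 10), bool), 100)


@settings(max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_positive_fraction_monotone_in_threshold(seed):
    rng = np.random.default_rng(seed)
    channel = Image2D(rng.integers(0, 256, (32, 32)).astype(np.uint8))
    region = np.ones((32, 32), bool)
    fracs = [oq.positive_pixel_fraction(channel, region, t) for t in range(0, 256, 16)]
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def test_detect_spots_on_zero_signal():
    channel = Image2D(np.full((64, 64), 10, np.uint8))
    assert oq.detect_spots(channel) == []
    with pytest.raises(ValueError):
        SpotConfig(min_sigma=3.0, max_sigma=1.0)


def test_detect_spots_matches_planted_spots():
    """Six well-separated planted puncta are each recovered within 2 px and
    assigned to the owning organoid."""
    channels, gt = oq.generate_confocal_scene(
        1, 1, {"counts": {1: 6, 2: 0}}, (256, 256), seed=5)
    detections = oq.detect_spots(channels[1], gt.true_mask)
    assert len(detections) == 6
    assert all(d.organoid_id == 1 for d in detections)
    for r, c in gt.true_spots[1]:
        err = min(math.hypot(d.centroid[0] - r, d.centroid[1] - c) for d in detections)
        assert err <= 2.0


def test_count_conservation_and_background_drop():
    dets = [
        oq.TuftDetection((1.0, 1.0), 50, 2.0, organoid_id=1),
        oq.TuftDetection((2.0, 2.0), 50, 2.0, organoid_id=1),
        oq.TuftDetection((3.0, 3.0), 50, 2.0, organoid_id=1),
        oq.TuftDetection((4.0, 4.0), 50, 2.0, organoid_id=0),
        oq.TuftDetection((5.0, 5.0), 50, 2.0, organoid_id=0),
    ]
    records = [OrganoidRecord(1, 10.0, 50.0)]
    res = oq.count_tufts_per_organoid(dets, records)
    assert res.counts == {1: 3}
    assert len(res.dropped) == 2
    assert res.total_assigned + len(res.dropped) == len(dets)
    with pytest.raises(ValueError, match="unknown organoid"):
        oq.count_tufts_per_organoid(
            [oq.TuftDetection((0.0, 0.0), 1, 1, organoid_id=9)], records)
    with pytest.raises(ValueError, match="rejected"):
        oq.count_tufts_per_organoid(
            dets, [OrganoidRecord(1, 10.0, 50.0, review_status="rejected")])


def test_curated_edits_adjust_counts():
    dets = [oq.TuftDetection((float(i), float(i)), 50, 2.0, organoid_id=1)
            for i in range(3)]
    records = [OrganoidRecord(1, 10.0, 50.0)]
    edits = pd.DataFrame([
        {"action": "remove", "organoid_id": 1, "row": 0.0, "col": 0.0},
        {"action": "add", "organoid_id": 1, "row": 30.0, "col": 30.0},
        {"action": "add", "organoid_id": 1, "row": 40.0, "col": 40.0},
    ])
    res = oq.count_tufts_per_organoid(dets, records, policy="curated",
                                      curated_edits=edits)
    assert res.counts == {1: 4}
    with pytest.raises(ValueError):
        oq.count_tufts_per_organoid(dets, records, policy="curated")


def test_fraction_high_tuft_contract():
    assert oq.fraction_high_tuft([0, 9, 12, 3], 8) == 50.0
    assert oq.fraction_high_tuft([8, 8, 8], 8) == 0.0  # strict "more than"
    assert oq.fraction_high_tuft([9, 10, 11], 8) == 100.0
    assert oq.fraction_high_tuft({1: 9, 2: 0}, 8) == 50.0
    with pytest.raises(ValueError):
        oq.fraction_high_tuft([], 8)


def test_tufts_by_class_split_and_conservation():
    records = [
        OrganoidRecord(1, 10.0, 50.0, "budding", 0.9),
        OrganoidRecord(2, 10.0, 50.0, "budding", 0.9),
        OrganoidRecord(3, 10.0, 50.0, "spheroid", 0.9),
        OrganoidRecord(4, 10.0, 50.0),
    ]
    counts = {1: 6, 2: 4, 3: 0, 4: 2}
    out = oq.tufts_by_class(counts, records)
    assert out["budding"]["mean"] == 5.0
    assert out["spheroid"]["counts"] == [0]
    assert out["unclassified"]["counts"] == [2]
    total = sum(sum(v["counts"]) for v in out.values())
    assert total == sum(counts.values())


def test_budding_only_spots_give_zero_spheroid_mean():
    _, gt = oq.generate_confocal_scene(2, 2, {"spheroid": 0.0, "budding": 4.0},
                                       (384, 384), seed=3)
    records = [OrganoidRecord(oid, 10.0, 50.0, cls, 1.0)
               for oid, cls in gt.true_classes.items()]
    counts = {oid: len(s) for oid, s in gt.true_spots.items()}
    out = oq.tufts_by_class(counts, records)
    assert out["spheroid"]["mean"] == 0.0


def test_roi_positive_ratio_two_roi_mode():
    px = np.zeros((20, 20), np.uint8)
    px[:10, :10] = 200  # 100 positive pixels in "crypt"
    px[10:, :5] = 200  # 50 positive pixels in "villus"
    channel = Image2D(px)
    rois = RoiSet({"crypt": np.zeros((20, 20), bool), "villus": np.zeros((20, 20), bool)})
    rois.regions["crypt"][:10] = True
    rois.regions["villus"][10:] = True
    res = oq.roi_positive_ratio(channel, rois, "crypt", "villus", 100)
    assert res.value == pytest.approx(2.0)
    # self-ratio is exactly 1
    self_res = oq.roi_positive_ratio(channel, rois, "crypt", "crypt", 100)
    assert self_res.value == 1.0
    # zero-positive denominator -> flagged undefined, not infinity
    undef = oq.roi_positive_ratio(channel, rois, "crypt", "villus", 250)
    assert not undef.defined and math.isnan(undef.value)
    with pytest.raises(KeyError):
        oq.roi_positive_ratio(channel, rois, "crypt", "missing", 100)


def test_roi_positive_ratio_two_channel_mode():
    marker = Image2D(np.full((10, 10), 150, np.uint8))
    nuclei = np.zeros((10, 10), np.uint8)
    nuclei[:, :5] = 200  # half the ROI is nuclear-positive
    channels = {"psmad2": marker, "dapi": Image2D(nuclei)}
    rois = RoiSet({"crypt": np.ones((10, 10), bool)})
    res = oq.roi_positive_ratio(channels, rois, "psmad2", "dapi",
                                {"psmad2": 100, "dapi": 100})
    assert res.value == pytest.approx(2.0)  # 100 positives / 50 positives


def test_proximity_ratio_arithmetic_and_uniform():
    shape = (100, 100)
    ref = np.zeros(shape, bool)
    rr, cc = draw_disk((50, 50), 6, shape=shape)
    ref[rr, cc] = True
    vicinity = ndi.binary_dilation(ref, np.ones((11, 11)))
    bg = np.zeros(shape, bool)
    bg[:20] = True
    signal = np.full(shape, 25.0)
    signal[vicinity] = 100.0
    res = oq.proximity_signal_ratio(Image2D(np.round(signal).astype(np.uint8)),
                                    ref, bg, dilation_radius=5)
    assert res.value == pytest.approx(4.0)
    uniform = oq.proximity_signal_ratio(Image2D(np.full(shape, 80, np.uint8)),
                                        ref, bg, dilation_radius=5)
    assert uniform.value == pytest.approx(1.0)


def test_proximity_ratio_invariant_to_zero_border():
    shape = (80, 80)
    rng = np.random.default_rng(2)
    signal = rng.integers(10, 200, shape).astype(np.uint8)
    ref = np.zeros(shape, bool)
    ref[38:42, 38:42] = True
    bg = np.zeros(shape, bool)
    bg[5:15, 5:15] = True
    base = oq.proximity_signal_ratio(Image2D(signal), ref, bg, 5)
    pad = 12
    signal_p = np.pad(signal, pad)
    ref_p = np.pad(ref, pad)
    bg_p = np.pad(bg, pad)
    padded = oq.proximity_signal_ratio(Image2D(signal_p), ref_p, bg_p, 5)
    assert padded.value == pytest.approx(base.value)


def _planted_cells(shape, centers, amplitude=150.0, sigma=2.5):
    deltas = np.zeros(shape)
    for r, c in centers:
        deltas[r, c] = amplitude * 2 * np.pi * sigma**2
    img = ndi.gaussian_filter(deltas, sigma) + 8.0
    return Image2D(np.clip(np.round(img), 0, 255).astype(np.uint8))


def test_count_positive_cells_recovers_planted_blobs():
    rng = np.random.default_rng(1)
    centers = []
    while len(centers) < 14:
        p = tuple(rng.integers(15, 110, 2))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= 144 for q in centers):
            centers.append(p)
    channel = _planted_cells((128, 128), centers)
    roi = np.zeros((128, 128), bool)
    roi[:, :] = True
    counts = oq.count_positive_cells(channel, RoiSet({"crypt": roi}))
    assert abs(counts["crypt"] - 14) <= 1
    with pytest.raises(ValueError, match="empty ROI"):
        oq.count_positive_cells(channel, RoiSet({"crypt": np.zeros((128, 128), bool)}))


def test_cell_counts_additive_over_disjoint_rois():
    rng = np.random.default_rng(4)
    centers = []
    while len(centers) < 10:
        p = tuple(rng.integers(15, 110, 2))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= 144 for q in centers):
            centers.append(p)
    channel = _planted_cells((128, 128), centers)
    whole = np.ones((128, 128), bool)
    left = whole.copy()
    left[:, 64:] = False
    right = whole & ~left
    counts = oq.count_positive_cells(channel, RoiSet({"whole": whole, "left": left,
                                                      "right": right}))
    assert counts["left"] + counts["right"] == counts["whole"]


def test_aggregate_by_subject_rules():
    values = {f"crypt{i}": float(i + 1) for i in range(5)}  # subject A: 1..5
    values.update({f"v{i}": 10.0 for i in range(4)})  # subject B: only 4 ROIs
    subject_map = {f"crypt{i}": "mouseA" for i in range(5)}
    subject_map.update({f"v{i}": "mouseB" for i in range(4)})
    means, excluded = oq.aggregate_by_subject(values, subject_map, min_rois=5)
    assert means == {"mouseA": 3.0}
    assert excluded == {"mouseB": 4}
    # invariance to ROI ordering
    shuffled = dict(reversed(list(values.items())))
    means2, _ = oq.aggregate_by_subject(shuffled, subject_map, min_rois=5)
    assert means2 == means
    with pytest.raises(ValueError, match="no subject"):
        oq.aggregate_by_subject({"orphan": 1.0}, {}, 5)
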