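import numpy as np
import pytest
from skimage.measure import label as cc_label
from skimage.measure import regionprops

import organoquant as oq
from organoquant.synthetic import PlacementError, SceneParams


def test_scene_object_counts_and_classes(small_scene):
    image, gt = small_scene
    assert gt.true_mask.n_objects == 5
    classes = list(gt.true_classes.values())
    assert classes.count("spheroid") == 3 and classes.count("budding") == 2
    assert image.pixels.shape == (512, 512)


def test_scene_determinism():
    a_img, a_gt = oq.generate_brightfield_scene(3, 2, (256, 256), seed=1)
    b_img, b_gt = oq.generate_brightfield_scene(3, 2, (256, 256), seed=1)
    np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
    np.testing.assert_array_equal(a_gt.true_mask.labels, b_gt.true_mask.labels)
    assert a_gt.true_classes == b_gt.true_classes
    c_img, _ = oq.generate_brightfield_scene(3, 2, (256, 256), seed=2)
    assert not np.array_equal(a_img.pixels, c_img.pixels)


def test_ground_truth_mask_is_consistent(small_scene):
    """Connected components equal the declared objects; objects darker than
    background; separation respected."""
    image, gt = small_scene
    labels = gt.true_mask.labels
    assert cc_label(labels > 0).max() == gt.true_mask.n_objects
    bg_mean = image.pixels[labels == 0].mean()
    for oid, gray in gt.true_gray.items():
        assert image.pixels[labels == oid].mean() < bg_mean
        assert abs(image.pixels[labels == oid].mean() - gray) < 8  # noise + shading


def test_budding_less_solid_than_spheroid_over_20_scenes():
    """Morphology classes are separable by construction: mean ground-truth
    solidity of budding objects is below that of spheroids."""
    sol = {"spheroid": [], "budding": []}
    for seed in range(20):
        _, gt = oq.generate_brightfield_scene(3, 3, (512, 512), seed=seed)
        for prop in regionprops(gt.true_mask.labels):
            sol[gt.true_classes[prop.label]].append(prop.solidity)
    assert np.mean(sol["budding"]) < np.mean(sol["spheroid"])
    assert np.mean(sol["spheroid"]) > 0.95


def test_placement_error_when_scene_is_overfull():
    with pytest.raises(PlacementError):
        oq.generate_brightfield_scene(40, 0, (128, 128), seed=0)


def test_confocal_fixed_counts_and_zero_amplitude():
    channels, gt = oq.generate_confocal_scene(
        1, 1, {"counts": {1: 6, 2: 0}}, (256, 256), seed=5)
    assert sorted(len(v) for v in gt.true_spots.values()) == [0, 6]
    # spots lie inside their organoid's mask
    for oid, spots in gt.true_spots.items():
        for r, c in spots:
            assert gt.true_mask.labels[r, c] == oid
    # amplitude 0 -> marker channel is pure background noise
    params = SceneParams(marker_peak=0.0)
    channels0, _ = oq.generate_confocal_scene(1, 1, {"counts": {1: 6, 2: 0}},
                                              (256, 256), params=params, seed=5)
    marker = channels0[1].pixels.astype(float)
    assert abs(marker.mean() - params.marker_background) < 1.0
    assert marker.max() < params.marker_background + 6 * params.marker_noise_sigma


def test_poisson_spot_law_sample_mean():
    """Over 20 seeded scenes the generated spot count per budding organoid
    matches the configured Poisson mean within 2 standard errors."""
    mean = 5.0
    counts = []
    for seed in range(20):
        _, gt = oq.generate_confocal_scene(
            2, 4, {"spheroid": 0.5, "budding": mean, "max": 12}, (512, 512), seed=seed)
        counts.extend(len(gt.true_spots[oid]) for oid, cls in gt.true_classes.items()
                      if cls == "budding")
    se = np.sqrt(mean / len(counts))  # Poisson variance = mean
    assert abs(np.mean(counts) - mean) < 2 * se + 0.2  # slack for the cap at 12


def test_degrade_scene_halves_measured_gray():
    image, gt = oq.generate_brightfield_scene(2, 1, (256, 256), seed=4)
    labels = gt.true_mask.labels
    original = {oid: float(image.pixels[labels == oid].mean()) for oid in gt.true_classes}
    degraded = oq.degrade_scene(image, gt, darkening_factor=0.5, seed=9)
    for oid, before in original.items():
        after = float(degraded.pixels[labels == oid].mean())
        assert after == pytest.approx(0.5 * before, rel=0.05)
        assert after < before  # strict monotonic decrease
        assert gt.true_gray[oid] == pytest.approx(0.5 * before, rel=0.1)


def test_degrade_factor_one_is_noise_only():
    image, gt = oq.generate_brightfield_scene(2, 1, (256, 256), seed=4)
    same = oq.degrade_scene(image, gt, darkening_factor=1.0, seed=9)
    diff = same.pixels.astype(float) - image.pixels.astype(float)
    assert np.abs(diff).mean() < 4 * SceneParams().noise_sigma
    with pytest.raises(ValueError):
        oq.degrade_scene(image, gt, darkening_factor=0.0)
    with pytest.raises(ValueError):
        oq.degrade_scene(image, gt, darkening_factor=1.5)


def test_zstack_wrapper_replicates_with_noise():
    image, _ = oq.generate_brightfield_scene(1, 0, (128, 128), seed=0)
    stack = oq.as_zstack(image, n_planes=4, plane_noise_sigma=1.0, seed=3)
    assert stack.n_planes == 4
    assert stack.plane_shape == image.shape
    assert not np.array_equal(stack.planes[0], stack.planes[1])
    # per-plane deviation stays at noise scale
    assert np.abs(stack.planes[0].astype(float) - image.pixels).mean() < 2.0
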