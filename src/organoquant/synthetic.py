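"""Synthetic organoid scenes with complete ground truth.

Brightfield scenes emulate what a transmitted-light projection of an
organoid culture looks like: a bright background (~0.8 of the dynamic
range) with darker organoid interiors (0.2–0.6 of range), so that dying
or stressed organoids can be modelled simply by darkening (lower mean
gray value). Two morphological classes are drawn:

* ``spheroid`` — a smooth ellipse (solidity near 1), the immature,
  round, thin-walled morphology;
* ``budding`` — a central body with 2–6 attached lobes ("buds"), giving
  visibly lower solidity, the mature crypt-bearing morphology.

Confocal scenes share the same object layout and add a nuclei channel
(dense small blobs inside each organoid) and a marker channel with
sparse bright Gaussian puncta — the tuft-cell staining pattern, which a
per-class count law can concentrate in budding organoids.

The noise model is additive Gaussian plus a mild multiplicative shading
field: enough realism to exercise thresholding and blob detection
without simulating optics. Scenes are 2-D projections; ``as_zstack``
wraps an image into a thin stack with per-plane noise for projection
tests. Every scene is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import resize

from .io import Image2D, LabelMask, ZStack


class PlacementError(RuntimeError):
    """Raised when objects or spots cannot be placed under the separation constraint."""


@dataclass
class SceneParams:
    """Generator settings. Intensities are on the 8-bit (0–255) scale."""

    # brightfield intensity layout: background bright, organoids darker
    background_gray: float = 204.0
    interior_gray_range: tuple[float, float] = (51.0, 153.0)
    noise_sigma: float = 3.0
    shading_amplitude: float = 0.03
    # geometry
    spheroid_radius_range: tuple[float, float] = (16.0, 34.0)
    spheroid_axis_ratio_range: tuple[float, float] = (0.75, 1.0)
    budding_body_radius_range: tuple[float, float] = (14.0, 26.0)
    lobe_count_range: tuple[int, int] = (2, 6)
    lobe_radius_frac_range: tuple[float, float] = (0.45, 0.7)
    min_separation: float = 15.0
    border_margin: float = 8.0
    max_retries: int = 300
    bit_depth: int = 8
    # confocal channels
    nuclei_background: float = 12.0
    nuclei_amplitude: float = 110.0
    nuclei_sigma: float = 2.2
    nuclei_density: float = 0.004  # nuclei per organoid pixel
    marker_background: float = 10.0
    marker_noise_sigma: float = 5.0
    marker_peak: float = 60.0  # peak SNR = marker_peak / marker_noise_sigma = 12
    spot_sigma: float = 2.0
    spot_min_separation: float = 8.0
    spot_edge_margin: float = 4.0


@dataclass
class SceneGroundTruth:
    """Sidecar truth for one generated scene."""

    true_mask: LabelMask
    true_classes: dict[int, str]
    true_gray: dict[int, float] = field(default_factory=dict)
    true_spots: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    seed: int = 0
    # noiseless brightfield render kept so controlled degradation can
    # re-apply noise from scratch (not part of the public truth tables)
    noiseless: np.ndarray | None = None
    params: SceneParams | None = None


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


def _spheroid_mask(shape, rng, params: SceneParams):
    r = rng.uniform(*params.spheroid_radius_range)
    ratio = rng.uniform(*params.spheroid_axis_ratio_range)
    theta = rng.uniform(0, np.pi)
    extent = r + 1.0
    lo, hi0 = params.border_margin + extent, shape[0] - params.border_margin - extent
    hi1 = shape[1] - params.border_margin - extent
    if hi0 <= lo or hi1 <= lo:
        return None
    cy, cx = rng.uniform(lo, hi0), rng.uniform(lo, hi1)
    mask = np.zeros(shape, bool)
    rr, cc = draw_ellipse(cy, cx, r, r * ratio, rotation=theta, shape=shape)
    mask[rr, cc] = True
    return mask


def _budding_mask(shape, rng, params: SceneParams):
    rb = rng.uniform(*params.budding_body_radius_range)
    k = rng.integers(params.lobe_count_range[0], params.lobe_count_range[1] + 1)
    fracs = rng.uniform(*params.lobe_radius_frac_range, size=k)
    base = rng.uniform(0, 2 * np.pi)
    jitter = rng.uniform(-0.25, 0.25, size=k) * (2 * np.pi / k)
    angles = base + 2 * np.pi * np.arange(k) / k + jitter
    extent = rb + float(np.max(fracs)) * rb * 1.55 + 1.0
    lo, hi0 = params.border_margin + extent, shape[0] - params.border_margin - extent
    hi1 = shape[1] - params.border_margin - extent
    if hi0 <= lo or hi1 <= lo:
        return None
    cy, cx = rng.uniform(lo, hi0), rng.uniform(lo, hi1)
    mask = np.zeros(shape, bool)
    rr, cc = draw_disk((cy, cx), rb, shape=shape)
    mask[rr, cc] = True
    for ang, frac in zip(angles, fracs):
        rl = frac * rb
        ly = cy + (rb + 0.55 * rl) * np.sin(ang)
        lx = cx + (rb + 0.55 * rl) * np.cos(ang)
        rr, cc = draw_disk((ly, lx), rl, shape=shape)
        mask[rr, cc] = True
    return mask


def _place_objects(n_spheroid: int, n_budding: int, shape, params: SceneParams, rng):
    """Greedy placement with a minimum-gap constraint between objects."""
    labels = np.zeros(shape, np.int32)
    forbidden = np.zeros(shape, bool)
    classes: dict[int, str] = {}
    kinds = ["spheroid"] * n_spheroid + ["budding"] * n_budding
    rng.shuffle(kinds)
    for oid, kind in enumerate(kinds, start=1):
        draw = _spheroid_mask if kind == "spheroid" else _budding_mask
        for _ in range(params.max_retries):
            mask = draw(shape, rng, params)
            if mask is None:
                continue
            if not (mask & forbidden).any():
                labels[mask] = oid
                near = ndi.distance_transform_edt(~mask) < params.min_separation
                forbidden |= near
                break
        else:
            raise PlacementError(
                f"could not place object {oid} ({kind}) after "
                f"{params.max_retries} retries at separation {params.min_separation}"
            )
        classes[oid] = kind
    return labels, classes


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _shading_field(shape, amplitude, rng):
    coarse = rng.normal(0.0, 1.0, (shape[0] // 64 + 2, shape[1] // 64 + 2))
    f = resize(coarse, shape, order=3, mode="reflect", anti_aliasing=False)
    peak = max(float(np.abs(f).max()), 1e-9)
    return 1.0 + amplitude * f / peak


def _finalize(noiseless, noise_sigma, shading_amplitude, bit_depth, rng):
    shading = _shading_field(noiseless.shape, shading_amplitude, rng)
    noisy = noiseless * shading + rng.normal(0.0, noise_sigma, noiseless.shape)
    hi = 2**bit_depth - 1
    return np.clip(np.round(noisy), 0, hi).astype(np.uint8 if bit_depth == 8 else np.uint16)


def generate_brightfield_scene(
    n_spheroid: int,
    n_budding: int,
    image_shape: tuple[int, int] = (512, 512),
    params: SceneParams | None = None,
    seed: int = 0,
    pixel_size_um: float = 1.0,
) -> tuple[Image2D, SceneGroundTruth]:
    """Render one brightfield scene and its complete ground truth."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    labels, classes = _place_objects(n_spheroid, n_budding, image_shape, params, rng)
    noiseless = np.full(image_shape, params.background_gray, dtype=np.float64)
    true_gray = {}
    for oid in classes:
        g = rng.uniform(*params.interior_gray_range)
        noiseless[labels == oid] = g
        true_gray[oid] = g
    pixels = _finalize(noiseless, params.noise_sigma, params.shading_amplitude,
                       params.bit_depth, rng)
    image = Image2D(pixels, channel="brightfield", pixel_size_um=pixel_size_um,
                    bit_depth=params.bit_depth)
    gt = SceneGroundTruth(
        true_mask=LabelMask(labels, pixel_size_um),
        true_classes=classes,
        true_gray=true_gray,
        seed=seed,
        noiseless=noiseless,
        params=params,
    )
    return image, gt


def _sample_spot_counts(classes: Mapping[int, str], law: Mapping, rng) -> dict[int, int]:
    """Per-organoid spot counts: explicit ``{"counts": {id: n}}`` or per-class
    Poisson means (e.g. ``{"spheroid": 0.5, "budding": 5.0, "max": 12}``)."""
    if "counts" in law:
        return {oid: int(law["counts"].get(oid, 0)) for oid in classes}
    cap = int(law.get("max", 10**9))
    out = {}
    for oid, cls in classes.items():
        mean = float(law.get(cls, 0.0))
        out[oid] = min(int(rng.poisson(mean)) if mean > 0 else 0, cap)
    return out


def _place_spots(mask: np.ndarray, count: int, params: SceneParams, rng):
    """Pick ``count`` spot centres inside one organoid, pairwise separated."""
    if count == 0:
        return []
    interior = ndi.distance_transform_edt(mask) > params.spot_edge_margin
    coords = np.argwhere(interior)
    if coords.size == 0:
        raise PlacementError("organoid too small to host any spot")
    min_d2 = params.spot_min_separation**2
    for _ in range(params.max_retries):
        order = rng.permutation(len(coords))
        chosen: list[tuple[int, int]] = []
        for idx in order:
            p = coords[idx]
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_d2 for q in chosen):
                chosen.append((int(p[0]), int(p[1])))
                if len(chosen) == count:
                    return chosen
    raise PlacementError(
        f"could not place {count} spots at separation {params.spot_min_separation}"
    )


def _render_confocal(labels, classes, counts, image_shape, params: SceneParams, rng,
                     pixel_size_um):
    # nuclei: dense small blobs within each organoid
    nuc_deltas = np.zeros(image_shape, np.float64)
    nuc_gain = 2 * np.pi * params.nuclei_sigma**2
    for oid in classes:
        mask = labels == oid
        area = int(mask.sum())
        n_nuc = max(3, int(round(params.nuclei_density * area)))
        coords = np.argwhere(mask)
        picks = coords[rng.integers(0, len(coords), size=n_nuc)]
        amps = params.nuclei_amplitude * rng.uniform(0.7, 1.3, size=n_nuc)
        for (r, c), a in zip(picks, amps):
            nuc_deltas[r, c] += a * nuc_gain
    nuclei = ndi.gaussian_filter(nuc_deltas, params.nuclei_sigma) + params.nuclei_background

    # marker: sparse bright puncta at the true spot positions
    true_spots: dict[int, list[tuple[int, int]]] = {}
    mark_deltas = np.zeros(image_shape, np.float64)
    spot_gain = 2 * np.pi * params.spot_sigma**2
    for oid in classes:
        spots = _place_spots(labels == oid, counts.get(oid, 0), params, rng)
        true_spots[oid] = spots
        for r, c in spots:
            mark_deltas[r, c] += params.marker_peak * spot_gain
    marker = ndi.gaussian_filter(mark_deltas, params.spot_sigma) + params.marker_background

    hi = 2**params.bit_depth - 1
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    nuc_px = np.clip(np.round(nuclei + rng.normal(0, params.marker_noise_sigma,
                                                  image_shape)), 0, hi).astype(dtype)
    mark_px = np.clip(np.round(marker + rng.normal(0, params.marker_noise_sigma,
                                                   image_shape)), 0, hi).astype(dtype)
    channels = [
        Image2D(nuc_px, channel="nuclei", pixel_size_um=pixel_size_um,
                bit_depth=params.bit_depth),
        Image2D(mark_px, channel="marker", pixel_size_um=pixel_size_um,
                bit_depth=params.bit_depth),
    ]
    return channels, true_spots


def generate_confocal_scene(
    n_spheroid: int,
    n_budding: int,
    spots_per_organoid_law: Mapping,
    image_shape: tuple[int, int] = (512, 512),
    params: SceneParams | None = None,
    seed: int = 0,
    pixel_size_um: float = 1.0,
) -> tuple[list[Image2D], SceneGroundTruth]:
    """Render a [nuclei, marker] confocal scene with known tuft-spot positions."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    labels, classes = _place_objects(n_spheroid, n_budding, image_shape, params, rng)
    counts = _sample_spot_counts(classes, spots_per_organoid_law, rng)
    channels, true_spots = _render_confocal(labels, classes, counts, image_shape,
                                            params, rng, pixel_size_um)
    gt = SceneGroundTruth(
        true_mask=LabelMask(labels, pixel_size_um),
        true_classes=classes,
        true_spots=true_spots,
        seed=seed,
        params=params,
    )
    return channels, gt


def generate_paired_scene(
    n_spheroid: int,
    n_budding: int,
    spots_per_organoid_law: Mapping,
    image_shape: tuple[int, int] = (512, 512),
    params: SceneParams | None = None,
    seed: int = 0,
    pixel_size_um: float = 1.0,
) -> tuple[Image2D, list[Image2D], SceneGroundTruth]:
    """One object layout rendered in both modalities (brightfield + confocal),
    so a full pipeline run can classify on brightfield and count tuft spots on
    the marker channel of the same organoids."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    labels, classes = _place_objects(n_spheroid, n_budding, image_shape, params, rng)

    noiseless = np.full(image_shape, params.background_gray, dtype=np.float64)
    true_gray = {}
    for oid in classes:
        g = rng.uniform(*params.interior_gray_range)
        noiseless[labels == oid] = g
        true_gray[oid] = g
    bf_px = _finalize(noiseless, params.noise_sigma, params.shading_amplitude,
                      params.bit_depth, rng)
    brightfield = Image2D(bf_px, channel="brightfield", pixel_size_um=pixel_size_um,
                          bit_depth=params.bit_depth)

    counts = _sample_spot_counts(classes, spots_per_organoid_law, rng)
    channels, true_spots = _render_confocal(labels, classes, counts, image_shape,
                                            params, rng, pixel_size_um)
    gt = SceneGroundTruth(
        true_mask=LabelMask(labels, pixel_size_um),
        true_classes=classes,
        true_gray=true_gray,
        true_spots=true_spots,
        seed=seed,
        noiseless=noiseless,
        params=params,
    )
    return brightfield, channels, gt


def degrade_scene(
    image: Image2D,
    ground_truth: SceneGroundTruth,
    darkening_factor: float,
    blur_scale: float = 0.0,
    seed: int = 0,
    object_ids: Sequence[int] | None = None,
) -> Image2D:
    """Darken selected organoids (dying phenotype) and re-apply seeded noise.

    Interior intensities are multiplied by ``darkening_factor`` on the
    noiseless render before noise, and ``ground_truth.true_gray`` is updated
    for the darkened objects.
    """
    if not 0 < darkening_factor <= 1:
        raise ValueError("darkening_factor must be in (0, 1]")
    if ground_truth.noiseless is None or ground_truth.params is None:
        raise ValueError("ground truth lacks the noiseless render needed for degradation")
    params = ground_truth.params
    noiseless = ground_truth.noiseless.copy()
    labels = ground_truth.true_mask.labels
    ids = list(object_ids) if object_ids is not None else list(ground_truth.true_classes)
    for oid in ids:
        noiseless[labels == oid] *= darkening_factor
        ground_truth.true_gray[oid] = ground_truth.true_gray.get(oid, 0.0) * darkening_factor
    if blur_scale > 0:
        noiseless = ndi.gaussian_filter(noiseless, blur_scale)
    rng = np.random.default_rng(seed)
    pixels = _finalize(noiseless, params.noise_sigma, params.shading_amplitude,
                       params.bit_depth, rng)
    return Image2D(pixels, channel=image.channel, pixel_size_um=image.pixel_size_um,
                   bit_depth=image.bit_depth)


def as_zstack(image: Image2D, n_planes: int = 3, plane_noise_sigma: float = 1.0,
              seed: int = 0) -> ZStack:
    """Wrap a 2-D scene into a thin z-stack: the plane replicated with
    independent per-plane noise, for exercising projection code."""
    rng = np.random.default_rng(seed)
    hi = 2**image.bit_depth - 1
    planes = [
        np.clip(np.round(image.pixels.astype(np.float64)
                         + rng.normal(0, plane_noise_sigma, image.shape)), 0, hi)
        for _ in range(n_planes)
    ]
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    return ZStack(np.stack(planes).astype(dtype), channel=image.channel,
                  pixel_size_um=image.pixel_size_um, bit_depth=image.bit_depth)


def generate_crop_dataset(
    n: int,
    seed: int = 0,
    params: SceneParams | None = None,
    crop_cfg=None,
    canvas: tuple[int, int] = (192, 192),
    segmented: bool = True,
):
    """Balanced labelled crop set for classifier training/evaluation.

    Draws one organoid per small canvas (alternating spheroid/budding),
    renders it with the brightfield noise model, and cuts the crop through
    the same segmentation + cropping path production images use, so the
    training distribution matches what the classifier sees at inference
    (segmented object boundaries, not the analytic ground-truth ones).
    Set ``segmented=False`` to crop from the true mask instead. Returns
    ``(crops, labels)`` with labels in {"spheroid", "budding"}.
    """
    # local imports: classify/segmentation do not import synthetic
    from .classify import make_crops
    from .segmentation import segment_brightfield

    params = params or SceneParams()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    crops, labels = [], []
    for i, s in enumerate(child_seeds):
        cls = "spheroid" if i % 2 == 0 else "budding"
        image, gt = generate_brightfield_scene(
            n_spheroid=1 if cls == "spheroid" else 0,
            n_budding=0 if cls == "spheroid" else 1,
            image_shape=canvas,
            params=params,
            seed=s,
        )
        mask = gt.true_mask
        if segmented:
            seg = segment_brightfield(image)
            if seg.n_objects == 1:
                mask = seg
        got = make_crops(image, mask, crop_cfg)
        assert len(got) == 1
        got[0].image_id = f"crop{i}"
        crops.append(got[0])
        labels.append(cls)
    return crops, labels
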