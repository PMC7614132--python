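"""Z-stack projection and classical brightfield segmentation.

Organoids in brightfield are darker than the background, so the default
projection for brightfield stacks is the pixelwise minimum (a dark object
in any focal plane survives), while confocal channels default to the
maximum projection. Segmentation itself is classical: Gaussian smoothing,
global thresholding (Otsu by default, fixed value for reproducibility),
hole filling, a minimum-area filter in µm², an optional distance-transform
watershed to split touching objects, and an optional border-object drop.
Deep learning is reserved for the classification stage; the segmentation
stage stays deterministic and parameter-transparent.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed

from .io import Image2D, LabelMask, OrganoidRecord, SegmentationParams, ZStack

PROJECTIONS = {"min": np.min, "max": np.max, "mean": np.mean}


def project_stack(stack: ZStack, method: str = "min") -> Image2D:
    """Reduce a z-stack to one plane by pixelwise min, max, or mean."""
    if stack.n_planes < 1:
        raise ValueError("cannot project an empty stack")
    if method not in PROJECTIONS:
        raise ValueError(f"unknown projection method {method!r}")
    reduced = PROJECTIONS[method](stack.planes.astype(np.float64), axis=0)
    return Image2D(reduced, channel=stack.channel, pixel_size_um=stack.pixel_size_um,
                   bit_depth=stack.bit_depth)


def _threshold(smoothed: np.ndarray, params: SegmentationParams, max_intensity: int) -> np.ndarray:
    if params.threshold_mode == "fixed":
        if params.threshold_value is None:
            raise ValueError("threshold_mode 'fixed' requires threshold_value")
        if not 0 <= float(params.threshold_value) <= max_intensity:
            raise ValueError(
                f"fixed threshold {params.threshold_value} outside the image "
                f"bit range [0, {max_intensity}]"
            )
    if np.ptp(smoothed) == 0:  # uniform image: nothing to segment
        return np.zeros(smoothed.shape, dtype=bool)
    if params.threshold_mode == "multi_otsu":
        # 3-class Otsu, keeping the threshold adjacent to the background mode:
        # robust when object interiors span a wide intensity range, where a
        # single Otsu threshold can cut off the objects nearest background
        try:
            t1, t2 = threshold_multiotsu(smoothed, classes=3)
            t = t2 if params.polarity == "dark_objects" else t1
        except ValueError:  # fewer than 3 distinct gray levels
            t = threshold_otsu(smoothed)
    elif params.threshold_mode == "otsu":
        t = threshold_otsu(smoothed)
    else:
        t = float(params.threshold_value)
    if params.polarity == "dark_objects":
        return smoothed < t
    return smoothed > t


def _split_touching(binary: np.ndarray, footprint: int) -> np.ndarray:
    """Distance-transform watershed; seeds are interior distance maxima,
    ties broken deterministically by lowest (row, col)."""
    distance = ndi.distance_transform_edt(binary)
    fp = np.ones((footprint, footprint), bool)
    peaks = peak_local_max(distance, footprint=fp, labels=cc_label(binary),
                           exclude_border=False)
    if len(peaks) == 0:
        return cc_label(binary).astype(np.int32)
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))  # (row, col) tie-break
    markers = np.zeros_like(binary, dtype=np.int32)
    for i, (r, c) in enumerate(peaks[order], start=1):
        markers[r, c] = i
    return watershed(-distance, markers, mask=binary).astype(np.int32)


def segment_brightfield(image: Image2D, params: SegmentationParams | None = None) -> LabelMask:
    """Segment organoid objects from background on a projected brightfield plane."""
    params = params or SegmentationParams()
    pixels = np.asarray(image.pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")

    smoothed = (gaussian(pixels, sigma=params.smoothing_sigma, preserve_range=True)
                if params.smoothing_sigma > 0 else pixels)
    binary = _threshold(smoothed, params, image.max_intensity)
    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)

    min_area_px = params.min_area_um2 / image.pixel_size_um**2
    labels = cc_label(binary).astype(np.int32)
    if min_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
        binary = labels > 0

    if params.split_touching:
        labels = _split_touching(binary, params.watershed_footprint)
        if min_area_px > 0:  # splitting can create sub-minimum fragments
            counts = np.bincount(labels.ravel())
            small = np.flatnonzero(counts < min_area_px)
            labels[np.isin(labels, small[small > 0])] = 0

    if params.border_policy == "drop":
        labels = clear_border(labels)

    return LabelMask(labels, image.pixel_size_um).compact()


def extract_features(mask: LabelMask, image: Image2D) -> list[OrganoidRecord]:
    """One record per labelled object: physical area, mean gray value on the
    native intensity scale, and the shape features (solidity, circularity,
    equivalent diameter) the fallback classifier uses."""
    if mask.labels.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} does not match image shape {image.shape}"
        )
    px = image.pixel_size_um
    records = []
    for prop in regionprops(mask.labels, intensity_image=np.asarray(image.pixels,
                                                                    dtype=np.float64)):
        area_px = prop.area
        perim = prop.perimeter if prop.perimeter > 0 else 1.0
        circularity = min(4 * np.pi * area_px / perim**2, 1.0)
        records.append(
            OrganoidRecord(
                organoid_id=int(prop.label),
                area_um2=float(area_px) * px**2,
                mean_gray=float(prop.intensity_mean),
                solidity=float(prop.solidity),
                circularity=float(circularity),
                equiv_diameter_um=float(prop.equivalent_diameter_area) * px,
            )
        )
    return records


# --------------------------------------------------------------------------
# evaluation against ground truth
# --------------------------------------------------------------------------


def match_objects(pred: LabelMask, truth: LabelMask, iou_threshold: float = 0.5):
    """Greedy one-to-one matching of predicted to true objects by descending
    IoU. Returns (matches, unmatched_pred, unmatched_true) where matches are
    (pred_id, true_id, iou) triples with IoU >= threshold."""
    pred_ids = pred.object_ids
    true_ids = truth.object_ids
    pairs = []
    # candidate pairs restricted to overlapping objects
    overlap = np.stack([pred.labels.ravel(), truth.labels.ravel()])
    both = (overlap[0] > 0) & (overlap[1] > 0)
    cand, counts = np.unique(overlap[:, both], axis=1, return_counts=True)
    pred_area = {int(i): int((pred.labels == i).sum()) for i in pred_ids}
    true_area = {int(i): int((truth.labels == i).sum()) for i in true_ids}
    for (pi, ti), inter in zip(cand.T, counts):
        union = pred_area[int(pi)] + true_area[int(ti)] - int(inter)
        pairs.append((float(inter) / union, int(pi), int(ti)))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_p, used_t, matches = set(), set(), []
    for iou, pi, ti in pairs:
        if iou < iou_threshold:
            break
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti, iou))
    unmatched_pred = [int(i) for i in pred_ids if int(i) not in used_p]
    unmatched_true = [int(i) for i in true_ids if int(i) not in used_t]
    return matches, unmatched_pred, unmatched_true


def evaluate_segmentation(pred: LabelMask, truth: LabelMask, iou_threshold: float = 0.5):
    """Object-detection precision/recall at an IoU matching threshold, plus
    the mean IoU over matched objects."""
    matches, unmatched_pred, unmatched_true = match_objects(pred, truth, iou_threshold)
    tp = len(matches)
    precision = tp / (tp + len(unmatched_pred)) if (tp + len(unmatched_pred)) else 1.0
    recall = tp / (tp + len(unmatched_true)) if (tp + len(unmatched_true)) else 1.0
    mean_iou = float(np.mean([m[2] for m in matches])) if matches else 0.0
    return {"precision": precision, "recall": recall, "mean_matched_iou": mean_iou,
            "n_matched": tp, "n_pred": int(pred.n_objects), "n_true": int(truth.n_objects)}
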