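"""Per-organoid and per-ROI marker quantification.

Covers the confocal read-outs of the pipeline:

* tuft-cell punctum detection (multi-scale Laplacian of Gaussian with
  non-maximum suppression) and per-organoid counting, with an optional
  curated-edit pass (add/remove rows) mirroring a manual count;
* positive-pixel fractions ("positive" = strictly above a set threshold);
* ROI ratio statistics — positive pixels of one marker over another in
  the same region (e.g. pSMAD2+/DAPI+), or the same marker across two
  regions (e.g. crypt over villus);
* proximity ratios — mean signal per pixel in the immediate vicinity of
  a reference structure (morphological dilation) over a background area;
* nucleus-scale positive-cell counts per ROI (e.g. OLFM4+ cells per
  crypt), aggregated to per-subject means with a minimum-ROI rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .io import Image2D, LabelMask, OrganoidRecord, SpotConfig


@dataclass
class TuftDetection:
    """One detected marker punctum."""

    centroid: tuple[float, float]  # (row, col)
    peak_intensity: float
    scale: float
    organoid_id: int = 0  # 0 = unassigned / background
    curated: bool = False


@dataclass
class RoiSet:
    """Named binary regions over one image (e.g. crypt, villus, background)."""

    regions: dict[str, np.ndarray]
    subject_id: str = ""

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(m).shape for name, m in self.regions.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"ROI shapes differ: {shapes}")
        self.regions = {name: np.asarray(m, dtype=bool) for name, m in self.regions.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.regions:
            raise KeyError(f"no ROI named {name!r}; have {sorted(self.regions)}")
        return self.regions[name]


@dataclass
class RatioResult:
    """A ratio that can be explicitly undefined (zero denominator)."""

    value: float
    defined: bool
    n_numerator: float = math.nan
    n_denominator: float = math.nan

    def __float__(self) -> float:
        return self.value


# --------------------------------------------------------------------------
# positive-pixel statistics
# --------------------------------------------------------------------------


def positive_pixel_fraction(channel: Image2D, region: np.ndarray, threshold: float) -> float:
    """Fraction of region pixels with intensity strictly above the threshold."""
    region = np.asarray(region, dtype=bool)
    if region.shape != channel.shape:
        raise ValueError("region shape does not match channel")
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    vals = np.asarray(channel.pixels)[region]
    return float(np.count_nonzero(vals > threshold)) / n


def _resolve_threshold(thresholds, name: str, channel: Image2D) -> float:
    if isinstance(thresholds, Mapping):
        if name in thresholds:
            t = thresholds[name]
        elif "default" in thresholds:
            t = thresholds["default"]
        else:
            raise KeyError(f"no threshold for {name!r}")
    else:
        t = thresholds
    if t == "otsu":
        return float(threshold_otsu(np.asarray(channel.pixels)))
    return float(t)


def roi_positive_ratio(channel, rois: RoiSet, numerator_name: str,
                       denominator_name: str, thresholds,
                       roi_name: str | None = None) -> RatioResult:
    """Ratio of positive-pixel counts.

    Two modes:

    * ``channel`` is a single :class:`Image2D`: the names are ROI names and
      the ratio is positives-in-ROI-A over positives-in-ROI-B of the same
      marker (crypt/villus style);
    * ``channel`` is a mapping of channel name -> Image2D: the names are
      channel names counted within one ROI (``roi_name``, or the only
      region), pSMAD2+/DAPI+ style.

    A zero-positive denominator yields an explicitly undefined result,
    never a silent infinity.
    """
    if isinstance(channel, Mapping):
        if roi_name is None:
            if len(rois.regions) != 1:
                raise ValueError("roi_name required when the ROI set has several regions")
            roi_name = next(iter(rois.regions))
        region = rois[roi_name]
        num_ch, den_ch = channel[numerator_name], channel[denominator_name]
        t_num = _resolve_threshold(thresholds, numerator_name, num_ch)
        t_den = _resolve_threshold(thresholds, denominator_name, den_ch)
        n_num = int(np.count_nonzero(np.asarray(num_ch.pixels)[region] > t_num))
        n_den = int(np.count_nonzero(np.asarray(den_ch.pixels)[region] > t_den))
    else:
        num_region, den_region = rois[numerator_name], rois[denominator_name]
        if not num_region.any() or not den_region.any():
            raise ValueError("both ROIs must be nonempty")
        t_num = _resolve_threshold(thresholds, numerator_name, channel)
        t_den = _resolve_threshold(thresholds, denominator_name, channel)
        px = np.asarray(channel.pixels)
        n_num = int(np.count_nonzero(px[num_region] > t_num))
        n_den = int(np.count_nonzero(px[den_region] > t_den))
    if n_den == 0:
        return RatioResult(math.nan, defined=False, n_numerator=n_num, n_denominator=0)
    return RatioResult(n_num / n_den, defined=True, n_numerator=n_num, n_denominator=n_den)


def proximity_signal_ratio(signal: Image2D, reference_mask: np.ndarray,
                           background_mask: np.ndarray,
                           dilation_radius: float = 5.0) -> RatioResult:
    """Mean signal per pixel in the immediate vicinity of the reference
    structure (its mask dilated by ``dilation_radius`` pixels) divided by
    the mean signal per pixel in the background area. Both areas may come
    from manually drawn ROIs."""
    ref = np.asarray(reference_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if ref.shape != signal.shape or bg.shape != signal.shape:
        raise ValueError("mask shapes do not match the signal image")
    vicinity = (ndi.binary_dilation(ref, structure=disk(int(round(dilation_radius))))
                if dilation_radius > 0 else ref)
    bg = bg & ~vicinity
    if not vicinity.any():
        raise ValueError("reference area empty after dilation")
    if not bg.any():
        raise ValueError("background area empty after excluding the dilated reference")
    px = np.asarray(signal.pixels, dtype=np.float64)
    mean_ref = float(px[vicinity].mean())
    mean_bg = float(px[bg].mean())
    if mean_bg == 0:
        return RatioResult(math.nan, defined=False, n_numerator=mean_ref, n_denominator=0.0)
    return RatioResult(mean_ref / mean_bg, defined=True,
                       n_numerator=mean_ref, n_denominator=mean_bg)


# --------------------------------------------------------------------------
# punctum detection and tuft counting
# --------------------------------------------------------------------------


def detect_spots(marker: Image2D, mask: LabelMask | None = None,
                 spot_cfg: SpotConfig | None = None) -> list[TuftDetection]:
    """Multi-scale LoG punctum detection with non-maximum suppression.

    Intensities are normalised to [0, 1] before detection, so the response
    threshold is bit-depth independent. Each surviving peak is assigned the
    label under its centroid (0 if background); an optional capture radius
    reassigns near-miss background detections to the nearest organoid.
    Deterministic: suppression order is by descending peak intensity with
    (row, col) tie-breaks.
    """
    cfg = spot_cfg or SpotConfig()
    if mask is not None and mask.labels.shape != marker.shape:
        raise ValueError("marker and mask shapes differ")
    img = np.asarray(marker.pixels, dtype=np.float64) / marker.max_intensity
    kwargs = dict(min_sigma=cfg.min_sigma, max_sigma=cfg.max_sigma, num_sigma=cfg.num_sigma)
    if cfg.threshold_mode == "fixed":
        blobs = blob_log(img, threshold=cfg.threshold, **kwargs)
    elif cfg.threshold_mode == "relative":
        blobs = blob_log(img, threshold=None, threshold_rel=cfg.threshold, **kwargs)
    else:
        raise ValueError(f"unknown threshold_mode {cfg.threshold_mode!r}")
    if len(blobs) == 0:
        return []
    peaks = np.array([img[int(round(r)), int(round(c))] for r, c, _ in blobs])
    order = np.lexsort((blobs[:, 1], blobs[:, 0], -peaks))
    kept: list[int] = []
    min_d2 = cfg.min_separation**2
    for i in order:
        r, c = blobs[i, 0], blobs[i, 1]
        if all((r - blobs[j, 0])**2 + (c - blobs[j, 1])**2 >= min_d2 for j in kept):
            kept.append(i)
    detections = []
    for i in sorted(kept, key=lambda j: (blobs[j, 0], blobs[j, 1])):
        r, c, s = blobs[i]
        ri, ci = int(round(r)), int(round(c))
        oid = 0
        if mask is not None:
            oid = int(mask.labels[ri, ci])
            if oid == 0 and cfg.capture_radius > 0:
                # reassign to the nearest labelled pixel within the capture radius
                d, idx = ndi.distance_transform_edt(mask.labels == 0, return_indices=True)
                if d[ri, ci] <= cfg.capture_radius:
                    oid = int(mask.labels[idx[0][ri, ci], idx[1][ri, ci]])
        detections.append(TuftDetection(centroid=(float(r), float(c)),
                                        peak_intensity=float(img[ri, ci]
                                                             * marker.max_intensity),
                                        scale=float(s), organoid_id=oid))
    return detections


@dataclass
class TuftCountResult:
    """Per-organoid tuft counts plus the detections dropped as background."""

    counts: dict[int, int]
    dropped: list[TuftDetection] = field(default_factory=list)

    @property
    def total_assigned(self) -> int:
        return int(sum(self.counts.values()))

    def __getitem__(self, oid: int) -> int:
        return self.counts[oid]


def _apply_curated_edits(detections: list[TuftDetection], edits) -> list[TuftDetection]:
    """Detection-level review: rows of (action in {add, remove}, organoid_id,
    row, col). ``remove`` deletes the detection of that organoid nearest to
    (row, col); ``add`` inserts a curated detection."""
    if isinstance(edits, (str, Path)):
        edits = pd.read_csv(edits)
    out = list(detections)
    for _, row in edits.iterrows():
        action = str(row["action"]).strip().lower()
        oid = int(row["organoid_id"])
        r, c = float(row["row"]), float(row["col"])
        if action == "add":
            out.append(TuftDetection(centroid=(r, c), peak_intensity=math.nan,
                                     scale=math.nan, organoid_id=oid, curated=True))
        elif action == "remove":
            cands = [i for i, d in enumerate(out) if d.organoid_id == oid]
            if not cands:
                raise ValueError(f"no detection to remove for organoid {oid}")
            best = min(cands, key=lambda i: (out[i].centroid[0] - r)**2
                       + (out[i].centroid[1] - c)**2)
            out.pop(best)
        else:
            raise ValueError(f"unknown curation action {action!r}")
    return out


def count_tufts_per_organoid(detections: Sequence[TuftDetection],
                             records: Sequence[OrganoidRecord],
                             policy: str = "auto",
                             curated_edits=None) -> TuftCountResult:
    """Count detections per organoid over the non-rejected records.

    Background-assigned detections (organoid_id 0) are dropped and reported;
    every organoid in ``records`` appears in the counts (zero included). The
    ``curated`` policy applies a detection-level review file before counting.
    """
    if any(r.review_status == "rejected" for r in records):
        raise ValueError("rejected records must be excluded before counting")
    known = {r.organoid_id for r in records}
    dets = list(detections)
    if policy == "curated":
        if curated_edits is None:
            raise ValueError("curated policy requires a curated_edits table")
        dets = _apply_curated_edits(dets, curated_edits)
    elif policy != "auto":
        raise ValueError(f"unknown counting policy {policy!r}")
    counts = {oid: 0 for oid in sorted(known)}
    dropped = []
    for d in dets:
        if d.organoid_id == 0:
            dropped.append(d)
        elif d.organoid_id in known:
            counts[d.organoid_id] += 1
        else:
            raise ValueError(f"detection references unknown organoid {d.organoid_id}")
    return TuftCountResult(counts=counts, dropped=dropped)


def fraction_high_tuft(counts, cutoff: int = 8) -> float:
    """Percentage of organoids with strictly more than ``cutoff`` tuft cells."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if not values:
        raise ValueError("fraction_high_tuft needs at least one organoid count")
    return 100.0 * sum(1 for v in values if v > cutoff) / len(values)


def tufts_by_class(counts: Mapping[int, int],
                   records: Sequence[OrganoidRecord]) -> dict[str, dict]:
    """Tuft-count distributions split by organoid class (spheroid/budding),
    with unclassified organoids reported separately."""
    by_id = {r.organoid_id: r for r in records}
    missing = [oid for oid in counts if oid not in by_id]
    if missing:
        raise ValueError(f"counts reference organoids without records: {missing}")
    out: dict[str, dict] = {}
    for cls in ("spheroid", "budding", "unclassified"):
        vals = [int(c) for oid, c in sorted(counts.items())
                if by_id[oid].class_label == cls]
        out[cls] = {"counts": vals, "n": len(vals),
                    "mean": float(np.mean(vals)) if vals else math.nan}
    return out


# --------------------------------------------------------------------------
# positive-cell counting and per-subject aggregation
# --------------------------------------------------------------------------


def count_positive_cells(channel: Image2D, rois: RoiSet,
                         cell_cfg: SpotConfig | None = None) -> dict[str, int]:
    """Nucleus-scale blob counts per ROI (e.g. OLFM4+ cells per crypt).

    Detection runs once over the whole channel and counts are taken by
    centroid membership, so counts are additive over disjoint ROIs.
    """
    cfg = cell_cfg or SpotConfig(min_sigma=2.0, max_sigma=6.0, num_sigma=5,
                                 threshold=0.08, min_separation=4.0)
    for name, region in rois.regions.items():
        if not region.any():
            raise ValueError(f"empty ROI {name!r}")
    detections = detect_spots(channel, mask=None, spot_cfg=cfg)
    out = {}
    for name, region in rois.regions.items():
        n = sum(1 for d in detections
                if region[int(round(d.centroid[0])), int(round(d.centroid[1]))])
        out[name] = int(n)
    return out


def aggregate_by_subject(values: Mapping[str, float], subject_map: Mapping[str, str],
                         min_rois: int = 5) -> tuple[dict[str, float], dict[str, int]]:
    """Per-subject means over ROI-level values (e.g. the mean over at least
    five crypts in one mouse). Subjects with fewer than ``min_rois`` ROIs are
    excluded and reported in the second return value (subject -> n ROIs)."""
    groups: dict[str, list[float]] = {}
    for roi_id, value in values.items():
        if roi_id not in subject_map:
            raise ValueError(f"ROI {roi_id!r} has no subject assignment")
        groups.setdefault(subject_map[roi_id], []).append(float(value))
    means, excluded = {}, {}
    for subject in sorted(groups):
        vals = groups[subject]
        if len(vals) < min_rois:
            excluded[subject] = len(vals)
        else:
            means[subject] = float(np.mean(vals))
    return means, excluded
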