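"""Image and table I/O plus the shared domain and parameter types.

Conventions used throughout the package:

* coordinates are 0-based ``(row, col)``, row-major;
* label masks are non-negative integer images where 0 is background and
  each object ``k > 0`` owns exactly the pixels labelled ``k``;
* physical areas are ``pixel count * pixel_size_um ** 2`` (µm²);
* intensities stay on the native bit-depth scale (8- or 16-bit), so a
  "gray value" of 204 in an 8-bit image means 204/255 of full scale.

Label masks are stored as 16-bit single-page TIFFs, image stacks as
multi-page TIFFs, and tabular outputs as UTF-8 CSV with fixed headers —
standard, diffable formats.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.segmentation import relabel_sequential

CLASS_LABELS = ("spheroid", "budding", "unclassified")
REVIEW_STATUSES = ("auto", "corrected", "rejected")

RECORD_COLUMNS = (
    "organoid_id",
    "area_um2",
    "mean_gray",
    "class_label",
    "confidence",
    "review_status",
    "image_id",
    "treatment",
)
#: optional feature/provenance columns appended after the fixed header
RECORD_EXTRA_COLUMNS = (
    "solidity",
    "circularity",
    "equiv_diameter_um",
    "previous_label",
)


class ImageFormatError(ValueError):
    """Raised when a file does not satisfy the pipeline's format contract."""


class ConfigurationError(ValueError):
    """Raised when required calibration or configuration is missing."""


def _check_intensity_range(arr: np.ndarray, bit_depth: int, what: str) -> None:
    if bit_depth not in (8, 16):
        raise ValueError(f"{what}: bit_depth must be 8 or 16, got {bit_depth}")
    hi = 2**bit_depth - 1
    if not arr.size:
        return
    amin, amax = float(np.min(arr)), float(np.max(arr))
    if amin < 0 or amax > hi:
        raise ValueError(
            f"{what}: intensities [{amin}, {amax}] outside [0, {hi}] "
            f"for bit depth {bit_depth}"
        )


@dataclass
class ZStack:
    """An ordered set of 2-D intensity planes from one channel.

    ``planes`` is indexed ``(z, row, col)``; all planes share shape.
    """

    planes: np.ndarray
    channel: str = ""
    pixel_size_um: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError(f"planes must be 3-D (z, row, col), got {self.planes.ndim}-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        _check_intensity_range(self.planes, self.bit_depth, "ZStack")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass
class Image2D:
    """A single 2-D intensity plane (one channel)."""

    pixels: np.ndarray
    channel: str = ""
    pixel_size_um: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got {self.pixels.ndim}-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        _check_intensity_range(self.pixels, self.bit_depth, "Image2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class LabelMask:
    """Integer object mask: 0 = background, k > 0 = pixels of object k."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids.size)

    def compact(self) -> "LabelMask":
        """Renumber labels to the contiguous range 1..N, preserving pixel sets."""
        relabeled, _, _ = relabel_sequential(self.labels)
        return LabelMask(relabeled.astype(self.labels.dtype), self.pixel_size_um)


@dataclass
class OrganoidRecord:
    """One segmented organoid with morphometrics and classification state.

    ``mean_gray`` is the mean brightfield intensity over the object's pixels
    on the native bit-depth scale (higher value is whiter; darker organoids
    are associated with dying). A corrected record keeps its pre-correction
    label in ``previous_label`` for provenance.
    """

    organoid_id: int
    area_um2: float
    mean_gray: float
    class_label: str = "unclassified"
    confidence: float = math.nan
    review_status: str = "auto"
    image_id: str = ""
    treatment: str = ""
    solidity: float = math.nan
    circularity: float = math.nan
    equiv_diameter_um: float = math.nan
    previous_label: str = ""

    def __post_init__(self) -> None:
        if self.organoid_id <= 0:
            raise ValueError("organoid_id must be a positive integer")
        if self.area_um2 <= 0:
            raise ValueError("area_um2 must be positive")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"invalid class_label {self.class_label!r}")
        if self.review_status not in REVIEW_STATUSES:
            raise ValueError(f"invalid review_status {self.review_status!r}")
        if self.class_label == "unclassified" and not math.isnan(self.confidence):
            raise ValueError("confidence is defined only for classified records")
        if self.class_label != "unclassified" and math.isnan(self.confidence):
            raise ValueError("classified records must carry a confidence")


# --------------------------------------------------------------------------
# parameter blocks (shared so every module reads the same config object)
# --------------------------------------------------------------------------


@dataclass
class SegmentationParams:
    """Classical segmentation knobs for projected brightfield images."""

    smoothing_sigma: float = 2.0
    threshold_mode: str = "multi_otsu"  # "multi_otsu", "otsu", or "fixed"
    threshold_value: float | None = None
    polarity: str = "dark_objects"  # or "bright_objects"
    fill_holes: bool = True
    min_area_um2: float = 200.0
    border_policy: str = "keep"  # or "drop"
    split_touching: bool = False
    watershed_footprint: int = 15

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.threshold_mode not in ("multi_otsu", "otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")


@dataclass
class CropConfig:
    """How organoid crops are cut for the classifier."""

    side: int = 128
    margin_frac: float = 0.15
    min_crop_pixels: int = 50
    pad_value: float = 0.0


@dataclass
class TrainConfig:
    """Classifier training settings (CNN or shape-feature fallback)."""

    kind: str = "cnn"  # "cnn" or "shape_features"
    epochs: int = 25
    batch_size: int = 32
    learning_rate: float = 2e-3
    val_fraction: float = 0.15
    decision_margin: float = 0.1


@dataclass
class SpotConfig:
    """Multi-scale (Laplacian-of-Gaussian) punctum detection settings."""

    min_sigma: float = 1.4
    max_sigma: float = 3.5
    num_sigma: int = 5
    threshold_mode: str = "fixed"  # "fixed" or "relative"
    threshold: float = 0.05  # LoG response on the [0, 1] intensity scale
    min_separation: float = 5.0
    capture_radius: float = 0.0  # px; 0 = drop background-assigned detections

    def __post_init__(self) -> None:
        if self.min_sigma <= 0 or self.max_sigma < self.min_sigma:
            raise ValueError("invalid scale range")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class QuantConfig:
    """Bundle of every tunable quantification parameter, serialisable to YAML.

    ``tuft_high_cutoff`` is a strict lower bound: an organoid counts as
    "high tuft" only with strictly more than ``tuft_high_cutoff`` tuft
    cells (default 8). ``min_rois_per_subject`` (default 5) is the minimum
    number of ROIs (e.g. crypts) a subject needs to enter per-subject means.
    """

    projection_method: dict = field(
        default_factory=lambda: {"brightfield": "min", "confocal": "max"}
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    crop: CropConfig = field(default_factory=CropConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    spots: SpotConfig = field(default_factory=SpotConfig)
    positive_thresholds: dict = field(default_factory=dict)  # marker -> intensity
    tuft_high_cutoff: int = 8
    min_rois_per_subject: int = 5
    pixel_size_um: float | None = None  # calibration override
    seed: int = 0

    def __post_init__(self) -> None:
        for name, thr in self.positive_thresholds.items():
            if thr < 0:
                raise ValueError(f"positive threshold for {name!r} must be >= 0")
        if self.tuft_high_cutoff < 0:
            raise ValueError("tuft_high_cutoff must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuantConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("segmentation", SegmentationParams),
            ("crop", CropConfig),
            ("train", TrainConfig),
            ("spots", SpotConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# TIFF I/O
# --------------------------------------------------------------------------


def _dtype_for(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth == 8 else np.dtype(np.uint16)


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    # only trust resolution tags with an explicit micrometre unit (ImageJ
    # convention); bare XResolution defaults are meaningless for microscopy
    meta = tf.imagej_metadata or {}
    if meta.get("unit") not in ("um", "micron", "µm"):
        return None
    tags = tf.pages[0].tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num:
            return float(den / num)
    return None


def read_zstack(
    path: str | Path,
    channel_map: Mapping[str, Sequence[int]] | None = None,
    pixel_size_um: float | None = None,
    channel: str = "",
) -> ZStack | list[ZStack]:
    """Read a multi-page TIFF as one z-stack, or several via ``channel_map``.

    ``channel_map`` maps channel names to page indices, resolving
    interleaved multi-channel files. Pixel size comes from TIFF metadata
    when present, else from the ``pixel_size_um`` override, else defaults
    to 1.0 µm with a warning (areas are then effectively in pixel² units).
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise ImageFormatError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        pages = []
        for i, page in enumerate(tf.pages):
            arr = page.asarray()
            if arr.ndim == 2:
                pages.append((i, arr))
            elif arr.ndim == 3:  # planar multi-sample page -> one plane per sample
                pages.extend((i, plane) for plane in arr)
            else:
                raise ImageFormatError(f"{path}: page {i} has unsupported shape {arr.shape}")
        if not pages:
            raise ImageFormatError(f"{path}: empty TIFF")
        shape0 = pages[0][1].shape
        for i, arr in pages:
            if arr.shape != shape0:
                raise ImageFormatError(
                    f"{path}: page {i} has shape {arr.shape}, expected {shape0}"
                )
        pages = [arr for _, arr in pages]
        meta_px = _pixel_size_from_tiff(tf)

    if meta_px is not None:
        px = meta_px
    elif pixel_size_um is not None:
        px = pixel_size_um
    else:
        warnings.warn(
            f"{path}: no pixel size in metadata and no override given; "
            "assuming 1.0 µm per pixel",
            stacklevel=2,
        )
        px = 1.0

    planes = np.stack(pages)
    bit_depth = 16 if planes.dtype.itemsize > 1 else 8
    if channel_map is None:
        return ZStack(planes, channel=channel, pixel_size_um=px, bit_depth=bit_depth)
    stacks = []
    for name, idx in channel_map.items():
        idx = list(idx)
        bad = [i for i in idx if i >= len(pages)]
        if bad:
            raise ImageFormatError(f"{path}: channel {name!r} references missing pages {bad}")
        stacks.append(
            ZStack(planes[idx], channel=name, pixel_size_um=px, bit_depth=bit_depth)
        )
    return stacks


def write_zstack(stack: ZStack, path: str | Path) -> None:
    """Write a z-stack as a multi-page TIFF with the pixel size recorded."""
    data = np.round(stack.planes).astype(_dtype_for(stack.bit_depth))
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        Path(path),
        data,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um", "axes": "ZYX"},
    )


def write_image(image: Image2D, path: str | Path) -> None:
    data = np.round(image.pixels).astype(_dtype_for(image.bit_depth))
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        Path(path), data, imagej=True, resolution=(res, res), metadata={"unit": "um"}
    )


def read_image(path: str | Path, pixel_size_um: float | None = None, channel: str = "") -> Image2D:
    stack = read_zstack(path, pixel_size_um=pixel_size_um, channel=channel)
    assert isinstance(stack, ZStack)
    if stack.n_planes != 1:
        raise ImageFormatError(f"{path}: expected a single-page image, got {stack.n_planes} pages")
    return Image2D(stack.planes[0], channel=channel, pixel_size_um=stack.pixel_size_um,
                   bit_depth=stack.bit_depth)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as a 16-bit single-page TIFF (lossless for <= 65535 objects)."""
    if mask.labels.size and mask.labels.max() > 65535:
        raise ImageFormatError(
            f"label mask has max id {int(mask.labels.max())}, exceeding 16-bit storage"
        )
    res = 1.0 / mask.pixel_size_um
    tifffile.imwrite(
        Path(path),
        mask.labels.astype(np.uint16),
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um"},
    )


def read_label_mask(path: str | Path, pixel_size_um: float | None = None) -> LabelMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        labels = tf.pages[0].asarray()
        meta_px = _pixel_size_from_tiff(tf)
    px = meta_px if meta_px is not None else (pixel_size_um if pixel_size_um else 1.0)
    return LabelMask(labels.astype(np.int32), pixel_size_um=px)


# --------------------------------------------------------------------------
# record tables
# --------------------------------------------------------------------------


def records_to_frame(records: Sequence[OrganoidRecord]) -> pd.DataFrame:
    cols = RECORD_COLUMNS + RECORD_EXTRA_COLUMNS
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    return pd.DataFrame(rows, columns=list(cols))


def write_records(records: Sequence[OrganoidRecord], path: str | Path) -> None:
    """Write organoid records as CSV with the fixed documented header."""
    records_to_frame(records).to_csv(Path(path), index=False)


def read_records(path: str | Path) -> list[OrganoidRecord]:
    """Read organoid records, validating every row (errors name the CSV line)."""
    df = pd.read_csv(Path(path), dtype={"image_id": str, "treatment": str,
                                        "previous_label": str}, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ImageFormatError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        kwargs = {
            "organoid_id": int(row["organoid_id"]),
            "area_um2": float(row["area_um2"]),
            "mean_gray": float(row["mean_gray"]),
            "class_label": str(row["class_label"]),
            "confidence": float(row["confidence"]) if pd.notna(row["confidence"]) else math.nan,
            "review_status": str(row["review_status"]),
            "image_id": "" if pd.isna(row.get("image_id")) else str(row.get("image_id", "")),
            "treatment": "" if pd.isna(row.get("treatment")) else str(row.get("treatment", "")),
        }
        for c in RECORD_EXTRA_COLUMNS:
            if c in df.columns and pd.notna(row[c]):
                kwargs[c] = str(row[c]) if c == "previous_label" else float(row[c])
        try:
            out.append(OrganoidRecord(**kwargs))
        except ValueError as exc:
            raise ImageFormatError(f"{path}: line {line_no}: {exc}") from exc
    return out
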