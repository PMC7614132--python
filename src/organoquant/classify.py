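"""Spheroid/budding classification of segmented organoids.

Each organoid is cut out of the projected brightfield image as a masked,
padded, square crop and classified by a compact convolutional network
(see :mod:`organoquant.nn`). A deterministic shape-feature fallback —
solidity, circularity, convexity-defect lobe count and a trained logistic
rule — is always available: it serves environments without the CNN's
compute budget and doubles as an interpretable cross-check of the CNN.

Class probabilities are reported in the fixed order (spheroid, budding).
Predictions inside the decision margin around 0.5, and crops too small to
classify, are left ``unclassified`` and queued for manual review; the
review cycle is a CSV round trip (export a sheet, edit corrected_class /
reject, apply), with corrected records keeping their pre-correction label
in provenance and rejected records excluded from all downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .io import CropConfig, Image2D, LabelMask, OrganoidRecord, TrainConfig
from .nn import SmallCNN

CLASS_MAP = ("spheroid", "budding")

REVIEW_COLUMNS = ("image_id", "organoid_id", "predicted_class", "confidence",
                  "corrected_class", "reject")


@dataclass
class OrganoidCrop:
    """One organoid patch: masked to the object, padded square, resampled
    to the configured side, intensities scaled to [0, 1]."""

    pixels: np.ndarray
    organoid_id: int
    image_id: str = ""
    pad_value: float = 0.0
    unclassifiable: bool = False


@dataclass
class ClassifierModel:
    """Trained classifier: either the compact CNN or the shape-feature
    logistic fallback. The class map is fixed to (spheroid, budding)."""

    kind: str
    cnn: SmallCNN | None = None
    scaler: StandardScaler | None = None
    logreg: LogisticRegression | None = None
    class_map: tuple[str, str] = CLASS_MAP
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, crops: Sequence[OrganoidCrop]) -> np.ndarray:
        """(n, 2) probabilities in class_map order; deterministic."""
        if self.kind == "cnn":
            x = np.stack([c.pixels for c in crops])
            return self.cnn.predict_proba(x)
        feats = np.array([crop_shape_features(c) for c in crops])
        raw = self.logreg.predict_proba(self.scaler.transform(feats))
        # sklearn orders columns by sorted class name; remap to class_map
        order = [list(self.logreg.classes_).index(name) for name in self.class_map]
        return raw[:, order]


def make_crops(image: Image2D, mask: LabelMask, crop_cfg: CropConfig | None = None
               ) -> list[OrganoidCrop]:
    """Cut one classifier crop per labelled object.

    Tight bounding box plus a fractional margin, non-object pixels set to
    the pad value, padded to a centred square and resampled to the
    configured side. Objects smaller than ``min_crop_pixels`` are emitted
    flagged unclassifiable.
    """
    cfg = crop_cfg or CropConfig()
    if mask.labels.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    scale = float(image.max_intensity)
    pixels = np.asarray(image.pixels, dtype=np.float64) / scale
    crops = []
    for prop in regionprops(mask.labels):
        oid = int(prop.label)
        if prop.area < cfg.min_crop_pixels:
            crops.append(OrganoidCrop(np.full((cfg.side, cfg.side), cfg.pad_value,
                                              dtype=np.float32),
                                      organoid_id=oid, pad_value=cfg.pad_value,
                                      unclassifiable=True))
            continue
        minr, minc, maxr, maxc = prop.bbox
        m = int(round(cfg.margin_frac * max(maxr - minr, maxc - minc)))
        r0, c0 = max(0, minr - m), max(0, minc - m)
        r1, c1 = min(image.shape[0], maxr + m), min(image.shape[1], maxc + m)
        sub = pixels[r0:r1, c0:c1]
        submask = mask.labels[r0:r1, c0:c1] == oid
        patch = np.where(submask, sub, cfg.pad_value)
        h, w = patch.shape
        side = max(h, w)
        square = np.full((side, side), cfg.pad_value, dtype=np.float64)
        top, left = (side - h) // 2, (side - w) // 2
        square[top:top + h, left:left + w] = patch
        out = resize(square, (cfg.side, cfg.side), order=1, preserve_range=True,
                     anti_aliasing=side > cfg.side).astype(np.float32)
        crops.append(OrganoidCrop(out, organoid_id=oid, pad_value=cfg.pad_value))
    return crops


def crop_shape_features(crop: OrganoidCrop) -> np.ndarray:
    """Shape descriptors of the crop's object support: solidity, circularity,
    convexity-defect lobe count, extent, eccentricity, filled-area fraction."""
    binary = crop.pixels > (crop.pad_value + 0.02)
    if not binary.any():
        return np.zeros(6)
    lab = cc_label(binary)
    props = regionprops(lab)
    big = max(props, key=lambda p: p.area)
    binary = lab == big.label
    hull = convex_hull_image(binary)
    hull_area = float(hull.sum())
    solidity = float(binary.sum()) / hull_area if hull_area else 0.0
    perim = big.perimeter if big.perimeter > 0 else 1.0
    circularity = min(4 * np.pi * big.area / perim**2, 1.0)
    # convexity defects above 1% of the hull area ~ inter-lobe notches
    defects = hull & ~binary
    dlab = cc_label(defects)
    sizes = np.bincount(dlab.ravel())[1:]
    n_lobe_defects = int(np.sum(sizes > 0.01 * hull_area))
    extent = float(big.extent)
    ecc = float(big.eccentricity)
    fill = float(big.area) / float(big.area_filled) if big.area_filled else 1.0
    return np.array([solidity, circularity, n_lobe_defects, extent, ecc, fill])


def train_classifier(labeled_crops: Sequence[tuple[OrganoidCrop, str]],
                     train_cfg: TrainConfig | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Train the CNN or the shape-feature fallback on labelled crops.

    A seeded stratification-free shuffle holds out ``val_fraction`` of the
    crops; held-out accuracy is recorded in the model metadata. Training is
    fully deterministic for a fixed seed and platform.
    """
    cfg = train_cfg or TrainConfig()
    if not labeled_crops:
        raise ValueError("no training crops given")
    labels = {lab for _, lab in labeled_crops}
    if not labels <= set(CLASS_MAP):
        raise ValueError(f"unknown class labels {labels - set(CLASS_MAP)}")
    if len(labels) < 2:
        raise ValueError("training requires both classes to be present")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labeled_crops))
    n_val = max(1, int(round(cfg.val_fraction * len(labeled_crops))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    y = np.array([CLASS_MAP.index(lab) for _, lab in labeled_crops])
    crops = [c for c, _ in labeled_crops]

    if cfg.kind == "cnn":
        x = np.stack([c.pixels for c in crops])
        net = SmallCNN(side=x.shape[1], seed=seed)
        history = net.fit(x[train_idx], y[train_idx], epochs=cfg.epochs,
                          batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                          x_val=x[val_idx], y_val=y[val_idx])
        val_acc = history[-1].get("val_accuracy", math.nan)
        return ClassifierModel(kind="cnn", cnn=net,
                               metadata={"seed": seed, "epochs": cfg.epochs,
                                         "n_train": len(train_idx),
                                         "validation_accuracy": val_acc})
    if cfg.kind == "shape_features":
        feats = np.array([crop_shape_features(c) for c in crops])
        scaler = StandardScaler().fit(feats[train_idx])
        logreg = LogisticRegression(max_iter=1000).fit(
            scaler.transform(feats[train_idx]),
            np.array([CLASS_MAP[i] for i in y])[train_idx])
        val_pred = logreg.predict(scaler.transform(feats[val_idx]))
        val_acc = float(np.mean(val_pred == np.array([CLASS_MAP[i] for i in y])[val_idx]))
        return ClassifierModel(kind="shape_features", scaler=scaler, logreg=logreg,
                               metadata={"seed": seed, "n_train": len(train_idx),
                                         "validation_accuracy": val_acc})
    raise ValueError(f"unknown classifier kind {cfg.kind!r}")


def classify_organoids(crops: Sequence[OrganoidCrop], model: ClassifierModel,
                       records: Sequence[OrganoidRecord],
                       decision_margin: float = 0.1) -> list[OrganoidRecord]:
    """Assign class labels and confidences to the matching records.

    Unclassifiable crops, and predictions with ``|p - 0.5| < decision_margin``,
    are left unclassified (review queue). Returns new records; inputs are
    not mutated.
    """
    by_id = {c.organoid_id: c for c in crops}
    classifiable = [c for c in crops if not c.unclassifiable]
    if classifiable:
        if model.kind == "cnn" and classifiable[0].pixels.shape[0] != model.cnn.side:
            raise ValueError(
                f"crop side {classifiable[0].pixels.shape[0]} does not match "
                f"model side {model.cnn.side}")
        probs = model.predict_proba(classifiable)
        prob_by_id = {c.organoid_id: p for c, p in zip(classifiable, probs)}
    else:
        prob_by_id = {}
    out = []
    for rec in records:
        crop = by_id.get(rec.organoid_id)
        if crop is None:
            raise ValueError(f"no crop for organoid {rec.organoid_id}")
        new = OrganoidRecord(**{f: getattr(rec, f) for f in rec.__dataclass_fields__})
        if crop.unclassifiable or abs(prob_by_id[rec.organoid_id][0] - 0.5) < decision_margin:
            new.class_label = "unclassified"
            new.confidence = math.nan
        else:
            p = prob_by_id[rec.organoid_id]
            k = int(np.argmax(p))
            new.class_label = model.class_map[k]
            new.confidence = float(p[k])
        out.append(new)
    return out


# --------------------------------------------------------------------------
# manual-correction cycle
# --------------------------------------------------------------------------


def export_review_sheet(records: Sequence[OrganoidRecord],
                        path: str | Path | None = None) -> pd.DataFrame:
    """One row per organoid: predicted class and confidence, with blank
    corrected_class and reject columns for the reviewer to fill in."""
    df = pd.DataFrame(
        [{"image_id": r.image_id, "organoid_id": r.organoid_id,
          "predicted_class": r.class_label,
          "confidence": r.confidence, "corrected_class": "", "reject": ""}
         for r in records],
        columns=list(REVIEW_COLUMNS),
    )
    if path is not None:
        df.to_csv(Path(path), index=False)
    return df


def _load_sheet(sheet) -> pd.DataFrame:
    if isinstance(sheet, (str, Path)):
        sheet = pd.read_csv(sheet, keep_default_na=False)
    missing = [c for c in REVIEW_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"review sheet missing columns {missing}")
    return sheet


def apply_corrections(records: Sequence[OrganoidRecord], sheet) -> list[OrganoidRecord]:
    """Apply a review sheet: corrected_class overrides the label (keeping the
    old one in provenance), reject excludes the record downstream. Idempotent
    for a fixed sheet; untouched rows pass through unchanged."""
    df = _load_sheet(sheet)
    by_key = {(r.image_id, r.organoid_id): r for r in records}
    edits: dict[tuple, tuple[str, bool]] = {}
    for _, row in df.iterrows():
        key = (str(row["image_id"]) if row["image_id"] == row["image_id"] else "",
               int(row["organoid_id"]))
        if key not in by_key:
            raise ValueError(f"review sheet references unknown organoid {key}")
        corrected = str(row["corrected_class"]).strip()
        if corrected.lower() in ("", "nan"):
            corrected = ""
        if corrected not in ("", "spheroid", "budding"):
            raise ValueError(f"invalid corrected_class {corrected!r} for organoid {key}")
        reject = str(row["reject"]).strip().lower() in ("1", "true", "yes", "x")
        edits[key] = (corrected, reject)
    out = []
    for rec in records:
        new = OrganoidRecord(**{f: getattr(rec, f) for f in rec.__dataclass_fields__})
        corrected, reject = edits.get((rec.image_id, rec.organoid_id), ("", False))
        if reject:
            new.review_status = "rejected"
        elif corrected and corrected != rec.class_label:
            new.previous_label = rec.class_label
            new.class_label = corrected
            new.confidence = 1.0
            new.review_status = "corrected"
        elif corrected:  # correction confirms the current label
            new.review_status = "corrected"
            if math.isnan(new.confidence):
                new.confidence = 1.0
        out.append(new)
    return out


def concordance(auto_records: Sequence[OrganoidRecord],
                corrected_records: Sequence[OrganoidRecord]) -> dict:
    """Agreement between automatic and corrected classifications: the
    fraction of matched organoids whose labels agree, plus the per-class
    confusion table (rows = automatic, columns = corrected)."""
    auto = {(r.image_id, r.organoid_id): r for r in auto_records}
    corr = {(r.image_id, r.organoid_id): r for r in corrected_records}
    if set(auto) != set(corr):
        raise ValueError("record sets do not cover the same organoids")
    keys = sorted(auto)
    a = [auto[k].class_label for k in keys]
    c = [corr[k].class_label for k in keys]
    agree = float(np.mean([x == y for x, y in zip(a, c)])) if keys else math.nan
    table = pd.crosstab(pd.Series(a, name="auto"), pd.Series(c, name="corrected"))
    return {"agreement": agree, "confusion": table, "n": len(keys)}
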