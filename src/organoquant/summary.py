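"""Treatment-level aggregation, group comparisons, plots, and the
end-to-end pipeline runner.

Per-treatment summaries report class percentages relative to the total
number of (non-rejected) organoids in that treatment, with an explicit
``unclassified`` bucket rather than renormalising over classified
organoids. Group comparisons are two-sample t-tests; Welch's unequal-
variance test is the unpaired default, with Student's and a paired
variant available, and every comparison records which variant (and which
unit of replication) was used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__  # noqa: E402
from .classify import classify_organoids, make_crops, train_classifier  # noqa: E402
from .io import (  # noqa: E402
    Image2D,
    LabelMask,
    OrganoidRecord,
    QuantConfig,
    write_image,
    write_label_mask,
    write_records,
)
from .quant import count_tufts_per_organoid, detect_spots, fraction_high_tuft  # noqa: E402
from .segmentation import extract_features, project_stack, segment_brightfield  # noqa: E402
from .synthetic import SceneParams, as_zstack, generate_crop_dataset, generate_paired_scene  # noqa: E402

log = logging.getLogger("organoquant")


@dataclass
class TreatmentSummary:
    treatment: str
    n_organoids: int
    percent_spheroid: float
    percent_budding: float
    percent_unclassified: float
    area_um2: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_gray: np.ndarray = field(default_factory=lambda: np.array([]))
    tuft_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    metric_means: dict = field(default_factory=dict)  # name -> (mean, sd)


@dataclass
class GroupComparison:
    metric: str
    groups: tuple[str, str]
    test: str
    statistic: float
    p_value: float
    n: tuple[int, int]
    two_tailed: bool = True
    unit: str = "organoid"


def summarize_treatment(records: Sequence[OrganoidRecord],
                        counts: Mapping[int, int] | None = None,
                        treatment_map: Mapping[str, str] | None = None
                        ) -> list[TreatmentSummary]:
    """Per-treatment class percentages and metric distributions.

    Rejected records never contribute; percentages are relative to the
    total number of organoids in that treatment and include the explicit
    unclassified bucket, so the three percentages sum to 100.
    """
    groups: dict[str, list[OrganoidRecord]] = {}
    for rec in records:
        treatment = rec.treatment or (treatment_map or {}).get(rec.image_id, "")
        if not treatment:
            raise ValueError(
                f"record {rec.image_id}/{rec.organoid_id} has no treatment label")
        groups.setdefault(treatment, []).append(rec)
    summaries = []
    for treatment in sorted(groups):
        kept = [r for r in groups[treatment] if r.review_status != "rejected"]
        if not kept:
            raise ValueError(f"no records in treatment {treatment!r} after rejection")
        n = len(kept)
        n_sph = sum(r.class_label == "spheroid" for r in kept)
        n_bud = sum(r.class_label == "budding" for r in kept)
        n_unc = n - n_sph - n_bud
        area = np.array(sorted(r.area_um2 for r in kept))
        gray = np.array(sorted(r.mean_gray for r in kept))
        tufts = (np.array(sorted(counts[r.organoid_id] for r in kept
                                 if r.organoid_id in counts))
                 if counts else np.array([]))
        metric_means = {
            "area_um2": (float(area.mean()), float(area.std(ddof=1)) if n > 1 else 0.0),
            "mean_gray": (float(gray.mean()), float(gray.std(ddof=1)) if n > 1 else 0.0),
        }
        if tufts.size:
            metric_means["tuft_count"] = (
                float(tufts.mean()), float(tufts.std(ddof=1)) if tufts.size > 1 else 0.0)
        summaries.append(TreatmentSummary(
            treatment=treatment, n_organoids=n,
            percent_spheroid=100.0 * n_sph / n,
            percent_budding=100.0 * n_bud / n,
            percent_unclassified=100.0 * n_unc / n,
            area_um2=area, mean_gray=gray, tuft_counts=tufts,
            metric_means=metric_means))
    return summaries


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   test: str = "welch_t", two_tailed: bool = True,
                   metric: str = "", groups: tuple[str, str] = ("a", "b"),
                   unit: str = "organoid") -> GroupComparison:
    """Two-sample t-test. Welch (unequal variances) is the unpaired default;
    ``student_t`` and ``paired_t`` are available. Two groups with zero
    variance and equal means give statistic 0 and p = 1."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "student_t":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "paired_t":
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    statistic, p = float(res.statistic), float(res.pvalue)
    if math.isnan(statistic) and a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        statistic, p = 0.0, 1.0
    if not two_tailed:
        p = p / 2 if statistic <= 0 else 1 - p / 2
    return GroupComparison(metric=metric, groups=groups, test=test,
                           statistic=statistic, p_value=p,
                           n=(len(a), len(b)), two_tailed=two_tailed, unit=unit)


# --------------------------------------------------------------------------
# plotting (presentation only)
# --------------------------------------------------------------------------

PLOT_KINDS = ("scatter_gray_vs_area", "count_histogram", "group_dots")


def plot_distributions(summaries: Sequence[TreatmentSummary], kind: str,
                       out_dir: str | Path) -> list[Path]:
    """Write one figure per treatment (or one combined dot plot)."""
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plt.rcParams["svg.hashsalt"] = "organoquant"
    paths: list[Path] = []
    if kind == "group_dots":
        fig, ax = plt.subplots(figsize=(4, 3))
        for i, s in enumerate(sorted(summaries, key=lambda s: s.treatment)):
            ax.plot([i] * len(s.area_um2), s.area_um2, "o", ms=3, alpha=0.6)
        ax.set_xticks(range(len(summaries)))
        ax.set_xticklabels([s.treatment for s in
                            sorted(summaries, key=lambda s: s.treatment)], rotation=45)
        ax.set_ylabel("area (µm²)")
        path = out_dir / "group_dots.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return [path]
    for s in summaries:
        if s.n_organoids == 0 or not s.area_um2.size:
            log.warning("skipping empty treatment %r", s.treatment)
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        if kind == "scatter_gray_vs_area":
            ax.scatter(s.mean_gray, s.area_um2, s=8, alpha=0.7)
            ax.set_xlabel("mean gray value (higher is whiter)")
            ax.set_ylabel("area (µm²)")
        else:  # count_histogram
            data = s.tuft_counts if s.tuft_counts.size else s.area_um2
            ax.hist(data, bins=20)
            ax.set_xlabel("tuft count" if s.tuft_counts.size else "area (µm²)")
            ax.set_ylabel("organoids")
        ax.set_title(f"{s.treatment} (n={s.n_organoids})")
        path = out_dir / f"{kind}_{s.treatment}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-benchmark pipeline run."""

    quant: QuantConfig = field(default_factory=QuantConfig)
    scene_params: SceneParams = field(default_factory=SceneParams)
    n_scenes: int = 3
    n_spheroid: int = 4
    n_budding: int = 4
    image_shape: tuple[int, int] = (384, 384)
    treatments: tuple[str, ...] = ("control",)
    spot_law: dict = field(default_factory=lambda: {"spheroid": 0.5, "budding": 5.0,
                                                    "max": 12})
    classifier_kind: str = "shape_features"
    n_training_crops: int = 240
    n_planes: int = 3


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute project -> segment -> features -> classify -> spots -> counts
    -> summaries on seeded synthetic scenes, writing masks, tables, a log and
    a machine-readable run manifest. Fully deterministic for a fixed config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seed = config.quant.seed
    stages = []
    try:
        stages.append("train_classifier")
        crops, labels = generate_crop_dataset(config.n_training_crops, seed=seed + 1000,
                                              params=config.scene_params,
                                              crop_cfg=config.quant.crop)
        train_cfg = dataclasses.replace(config.quant.train, kind=config.classifier_kind)
        model = train_classifier(list(zip(crops, labels)), train_cfg, seed=seed + 1001)
        log.info("classifier trained: %s", model.metadata)

        all_records: list[OrganoidRecord] = []
        all_counts: dict[int, int] = {}
        detection_rows = []
        offset = 0
        for i in range(config.n_scenes):
            image_id = f"scene{i}"
            treatment = config.treatments[i % len(config.treatments)]
            try:
                stages.append(f"{image_id}:generate")
                brightfield, channels, gt = generate_paired_scene(
                    config.n_spheroid, config.n_budding, config.spot_law,
                    config.image_shape, config.scene_params, seed=seed + i)
                stages.append(f"{image_id}:project")
                stack = as_zstack(brightfield, n_planes=config.n_planes,
                                  seed=seed + 5000 + i)
                projected = project_stack(
                    stack, config.quant.projection_method.get("brightfield", "min"))
                stages.append(f"{image_id}:segment")
                mask = segment_brightfield(projected, config.quant.segmentation)
                write_label_mask(mask, out_dir / f"{image_id}_mask.tif")
                write_image(brightfield, out_dir / f"{image_id}_brightfield.tif")
                stages.append(f"{image_id}:features")
                records = extract_features(mask, projected)
                stages.append(f"{image_id}:classify")
                obj_crops = make_crops(projected, mask, config.quant.crop)
                records = classify_organoids(obj_crops, model, records,
                                             config.quant.train.decision_margin)
                stages.append(f"{image_id}:spots")
                marker = channels[1]
                detections = detect_spots(marker, mask, config.quant.spots)
                stages.append(f"{image_id}:counts")
                result = count_tufts_per_organoid(detections, records)
                for rec in records:
                    rec.image_id = image_id
                    rec.treatment = treatment
                    # give organoids globally unique ids in the pooled tables
                for d in detections:
                    detection_rows.append({"image_id": image_id,
                                           "row": d.centroid[0], "col": d.centroid[1],
                                           "peak_intensity": d.peak_intensity,
                                           "scale": d.scale,
                                           "organoid_id": d.organoid_id})
                for rec in records:
                    all_counts[offset + rec.organoid_id] = result.counts[rec.organoid_id]
                for rec in records:
                    rec.organoid_id += offset
                offset += mask.n_objects
                all_records.extend(records)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {stages[-1]!r} failed for {image_id}: {exc}"
                ) from exc

        stages.append("summarize")
        write_records(all_records, out_dir / "records.csv")
        pd.DataFrame(detection_rows).to_csv(out_dir / "detections.csv", index=False)
        pd.DataFrame([{"organoid_id": k, "tuft_count": v}
                      for k, v in sorted(all_counts.items())]
                     ).to_csv(out_dir / "counts.csv", index=False)
        summaries = summarize_treatment(all_records, all_counts)
        pd.DataFrame([{
            "treatment": s.treatment, "n_organoids": s.n_organoids,
            "percent_spheroid": s.percent_spheroid,
            "percent_budding": s.percent_budding,
            "percent_unclassified": s.percent_unclassified,
            "mean_area_um2": s.metric_means["area_um2"][0],
            "sd_area_um2": s.metric_means["area_um2"][1],
            "mean_gray": s.metric_means["mean_gray"][0],
        } for s in summaries]).to_csv(out_dir / "summaries.csv", index=False)
        report = {
            "n_organoids": len(all_records),
            "fraction_high_tuft_percent": fraction_high_tuft(
                all_counts, config.quant.tuft_high_cutoff),
            "treatments": {s.treatment: s.n_organoids for s in summaries},
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest = {
            "package": "organoquant",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": seed,
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
            "stages": stages,
            "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          sort_keys=True))
        log.info("pipeline complete: %d organoids", len(all_records))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out_dir
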