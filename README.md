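# organoquant

Quantitative image analysis for intestinal organoid cultures: segmentation of
brightfield organoid fields, convolutional spheroid-vs-budding morphology
classification with a manual-correction cycle, and per-organoid confocal
marker quantification (tuft-cell counting, positive-pixel fractions, ROI
ratio statistics). It is aimed at labs that image organoid cultures under
cytokine or drug treatments and need per-organoid morphometrics and marker
read-outs at the scale of hundreds to thousands of organoids per condition.

## What it computes

Intestinal organoids grow as a mixed population of immature, round
**spheroids** and mature **budding** organoids with crypt-like protrusions;
treatments shift the balance between the two and change overall health
(dying organoids appear darker in brightfield, i.e. lower mean gray value).
The pipeline is:

1. **Projection + segmentation.** Brightfield z-stacks are reduced by a
   minimum projection (organoids are darker than background), smoothed with
   a Gaussian (σ = 2 px), thresholded (3-class Otsu by default, taking the
   threshold adjacent to the background mode), hole-filled, filtered by a
   minimum area in µm², and optionally split at touching boundaries by a
   distance-transform watershed. Each object k gets area
   `A_k = N_k · s²` (pixel count times squared pixel size) and mean gray
   value `ḡ_k = (1/N_k) Σ_{p∈k} I(p)` on the native bit-depth scale.
2. **Classification.** Each organoid is cut as a masked, padded 128×128
   crop and classified spheroid/budding by a compact three-block CNN
   (or by a logistic rule over shape features — solidity, circularity,
   convexity-defect lobe count). Predictions inside a decision margin
   around p = 0.5 stay `unclassified` and are queued for manual review;
   review-sheet corrections override labels and rejections exclude
   organoids from all downstream statistics.
3. **Marker quantification.** Tuft-cell puncta are detected on the
   max-projected marker channel by multi-scale Laplacian-of-Gaussian
   detection with non-maximum suppression and assigned to the organoid
   under the centroid. Positive pixels are defined strictly above a set
   threshold; ratio statistics cover positive-pixel ratios across ROIs or
   channels (e.g. crypt/villus, pSMAD2+/DAPI+), proximity ratios (mean
   signal in the dilated vicinity of a reference structure over
   background), per-ROI cell counts, and per-subject means with a
   minimum-ROI rule (default: at least 5 crypts per mouse). The high-tuft
   statistic is `100 · #{organoids with count > 8} / #organoids` (strict
   inequality; cutoff configurable).
4. **Summaries and tests.** Per-treatment class percentages (relative to
   all organoids in that treatment, with an explicit unclassified bucket)
   and two-sample t-tests (Welch default, Student's and paired variants).

Because raw study images are rarely shareable, the package ships a
synthetic scene generator with complete ground truth (object masks,
classes, interior gray values, tuft-spot coordinates), so the whole stack
is verifiable end to end: segmentation recovery, classifier accuracy, and
spot-count recovery are all measured against generated truth.

## Worked example

```bash
python examples/01_simulate_and_segment.py
```

```
true objects:      15
segmented objects: 15
precision=1.000 recall=1.000 mean matched IoU=0.934
first organoid: area=4892 um^2, mean gray=121.9, solidity=0.827
```

All 15 generated organoids are recovered with no false objects, and matched
masks overlap ground truth at IoU 0.93. The per-organoid record carries the
physical area, the mean brightfield gray value (higher is whiter; darker
organoids are associated with dying), and the shape features used by the
fallback classifier.

```bash
python examples/03_count_tuft_cells.py
```

```
detections: 29 (0 background-dropped)
  organoid 1 (budding): counted 3, true 3
  organoid 2 (budding): counted 10, true 10
  ...
mean tuft count: budding 5.20, spheroid 1.00
organoids with more than 8 tuft cells: 12.5%
```

Every planted punctum is recovered and assigned to the right organoid; the
per-class means reproduce the budding-enriched pattern the scene was
generated with, and the high-tuft percentage applies the strict "more
than 8" rule. The other examples cover classifier training with the
review cycle (`02`) and ROI ratio statistics with per-subject aggregation
and group comparisons (`04`).

A thin CLI wraps the same functions
(`organoquant simulate|segment|train|classify|review|quant|summarize|run`);
`organoquant run --out DIR --seed 0` executes the full seeded pipeline and
writes masks, record/count tables, summaries, a log, and a run manifest
sufficient to reproduce the run bit-for-bit.

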