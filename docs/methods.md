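# Methods

This note documents the models, algorithms, parameter choices and known
limitations of organoquant, in the package's own terms.

## Problem setting

Small-intestinal organoids are imaged as brightfield z-stacks (whole-well
fields of 5–50 organoids) and as multichannel confocal z-stacks (nuclei
plus one or more immunofluorescence/RNAscope marker channels). The
analysis tasks are (i) finding and measuring every organoid, (ii) calling
its morphology class — round immature *spheroid* vs lobed mature *budding*
organoid, (iii) counting sparse punctate marker signal (tuft cells, marker
DCLK1) per organoid, and (iv) ratio statistics over drawn regions of
tissue sections (crypt/villus, marker/nuclear, signal-near-structure over
background). Treatments are compared by class percentages and two-sample
t-tests.

## Segmentation

Brightfield organoids are darker than the background, so stacks are
reduced by a **minimum projection** (default; confocal channels use the
maximum). The projected image is smoothed (Gaussian, `smoothing_sigma`
default 2 px), thresholded, hole-filled, and filtered by `min_area_um2`
(default 200 µm²). Touching objects can be split by a watershed on the
negated interior distance transform, seeded at distance maxima within a
configurable footprint (default 15 px), with ties broken at the lowest
(row, col) for determinism. Border objects are kept by default
(`border_policy="drop"` available). Labels are compacted to 1..N.

**Thresholding.** The default mode is 3-class multi-Otsu, keeping the
threshold adjacent to the background mode. With a single global Otsu
threshold, organoid interiors spanning a wide range (0.2–0.6 of dynamic
range against a ~0.8 background) can straddle the threshold: the
between-class optimum then cuts off the palest organoids, which we
measured as a 5–17% recall loss on wide-intensity scenes. The three-class
split separates "background" from "all objects" robustly. Plain `otsu`
and `fixed(value)` modes remain available; fixed values are validated
against the image bit range. Uniform images segment to zero objects.

Physical units: `area_um2 = pixel count × pixel_size_um²`. Pixel size is
read from TIFF metadata only when an explicit micrometre unit is recorded
(ImageJ convention); otherwise a user override applies, else 1.0 µm with
a warning — physical-unit outputs are only as good as the calibration
supplied, since magnification is acquisition-specific.

## Classification

Each labelled object is cropped with a tight bounding box plus a 15%
margin, masked to the object (non-object pixels set to the pad value),
padded to a centred square, and resampled to 128×128 with intensities
scaled to [0, 1]. Objects under `min_crop_pixels` (default 50 px) are
flagged unclassifiable.

**CNN.** A compact, fully seeded NumPy network: 2×2 average-pool input
downsampling, three 3×3 convolution blocks (8/16/32 filters, ReLU, 2×2
max-pool after the first two), global average pooling, and a dense
softmax head; trained with Adam (default 25 epochs, batch 32, learning
rate 2e-3) and softmax cross-entropy, holding out 15% of crops for
validation. Training a 1,000-crop set takes about a minute on one CPU and
is bit-reproducible for a fixed seed and platform.

**Shape-feature fallback.** A logistic regression (standardised inputs)
over six deterministic descriptors of the crop support: solidity,
circularity (4πA/P², capped at 1), the number of convexity defects larger
than 1% of the hull area (a lobe-count proxy), extent, eccentricity, and
the filled-area fraction. It is interpretable, trains in seconds, and
doubles as an independent cross-check of the CNN (the two agree on ≥80%
of a default synthetic set).

Training crops are cut **through the segmentation path** (each
single-organoid canvas is segmented, and the crop masked by the segmented
object), so the training distribution matches inference. Masking by the
analytic ground-truth boundary instead introduces a domain shift —
segmented boundaries carry a thin bright background rim — that measurably
biased the CNN toward the budding class at inference.

Predictions with |p − 0.5| below `decision_margin` (default 0.1), and
unclassifiable crops, are left `unclassified` and routed to review. The
class set is closed to {spheroid, budding}; darkness/dying is treated as
a continuous gray-value annotation, not a class. Review is a CSV sheet
(one row per organoid): a corrected class overrides the label (the prior
label is kept in provenance and confidence is set to 1), a reject flag
excludes the organoid from every downstream statistic. Applying a sheet
is idempotent.

## Confocal quantification

**Punctum detection** runs multi-scale Laplacian of Gaussian (σ 1.4–3.5,
5 scales) on the [0, 1]-normalised max projection, thresholding the LoG
response (default fixed 0.05) and applying greedy non-maximum suppression
at `min_separation` (default 5 px), ordered by descending peak intensity
with (row, col) tie-breaks for determinism. Each surviving peak is
assigned the mask label under its centroid; background-assigned
detections are dropped (and reported) unless a capture radius reassigns
them to the nearest organoid. Counting supports an `auto` policy and a
`curated` policy that first applies a detection-level review table
(add/remove rows) — modelling manual curation purely as detection edits.

**Positive pixels** are strictly above the per-marker threshold
(configurable; Otsu available as an automatic default). Ratio statistics:

* `roi_positive_ratio` — positive-count ratios, either one channel across
  two ROIs (crypt/villus) or two channels in one ROI (pSMAD2+/DAPI+). A
  zero-positive denominator returns an explicitly undefined result.
* `proximity_signal_ratio` — mean signal per pixel within the reference
  mask dilated by `dilation_radius` (default 5 px ≙ 5 µm at 1 µm/px;
  "immediate vicinity" is operationalised as morphological dilation, and
  manually drawn ROIs are accepted), divided by the mean over the
  background area (dilated reference excluded).
* `count_positive_cells` — nucleus-scale blob counts per ROI; detection
  runs once per image and counts by centroid membership, making counts
  additive over disjoint ROIs.
* `aggregate_by_subject` — per-subject means with subjects under
  `min_rois_per_subject` (default 5, e.g. crypts per mouse) excluded and
  reported.

The high-tuft statistic uses a strict inequality (`count > cutoff`,
default cutoff 8) and errors on empty input rather than returning 0.

## Statistics

`compare_groups` wraps two-sample t-tests: Welch (default unpaired, the
safer choice under unequal variances), Student's, and a paired variant
requiring equal n. Two zero-variance groups with equal means return
statistic 0 and p = 1. The unit of replication (organoid vs
mouse/replicate) must be declared per comparison; no multiple-testing
correction is applied by default. Treatment summaries report class
percentages relative to all non-rejected organoids in the treatment,
including an explicit unclassified bucket (percentages sum to 100).

## Synthetic scenes

The generator renders what each analysis stage needs to be testable, as a
pure function of (parameters, seed):

* **Geometry** — spheroids are ellipses (axis ratio 0.75–1, radius 16–34
  px); budding organoids are a body disk (radius 14–26 px) with 2–6
  attached lobe disks (0.45–0.7 of body radius). Lobe count, not texture,
  carries the class signal, so both a shape classifier and a CNN can
  learn it. Objects are placed greedily with a minimum gap (default 15
  px, EDT-checked); infeasible requests raise a placement error after
  bounded retries.
* **Brightfield intensity** — background ≈ 0.8 of the 8-bit range (204),
  interiors 0.2–0.6 (51–153), additive Gaussian noise (σ 3) plus a mild
  multiplicative shading field (±3%, bicubically upsampled coarse noise).
  `degrade_scene` multiplies selected interiors by a darkening factor on
  the noiseless render before re-applying seeded noise — the dying-
  organoid phenotype as a controlled intensity manipulation.
* **Confocal channels** — nuclei as dense Gaussian blobs (σ 2.2, ~0.004
  nuclei/pixel of organoid area); tuft puncta as Gaussian peaks (σ 2,
  amplitude 60 over noise σ 5, peak SNR 12) at ground-truth positions
  placed ≥ 8 px apart and ≥ 4 px inside the organoid. Per-organoid counts
  follow per-class laws (Poisson means, optionally capped, or explicit
  counts), allowing the budding-enriched tuft pattern.
* **Z-stacks** — scenes are 2-D projections; `as_zstack` replicates a
  plane with independent per-plane noise for projection tests.

What the generator does **not** emulate: real organoid texture (lumen,
debris, out-of-focus halos), overlapping/mounded organoids, uneven
illumination beyond mild shading, autofluorescence, or 3-D structure.
Passing the synthetic benchmarks therefore demonstrates correctness of
the algorithms and their contracts — not segmentation or classification
accuracy on any particular microscope's real data, where thresholds,
scale ranges and the classifier need recalibration. Generator defaults
were chosen for class separability and placement feasibility, since no
quantitative morphology statistics (diameters, lobe counts) were
available to match.

## Benchmark problem sizes

The verification suite uses 20 seeded 512×512 brightfield scenes (5–20
objects each) for segmentation recovery; 1,000 training plus 200 held-out
crops for the classifiers; 20 confocal scenes (10 organoids each,
per-organoid counts 0–12) for spot-count recovery; and a 3-scene pipeline
run for end-to-end reproducibility. These sizes give tight sampling error
on the reported fractions while keeping the whole suite to a few minutes
on a single CPU.

## Known limitations

* Segmentation is 2-D on the projection; organoids overlapping in z are
  merged (the watershed split handles touching, not stacked, objects).
* The CNN is trained per-deployment on synthetic or curated crops; no
  pretrained weights ship with the package.
* Spot detection assumes approximately isotropic puncta within the
  configured scale range; RNAscope dot-size spectral analysis is out of
  scope.
* Physical-unit outputs depend entirely on supplied pixel-size
  calibration.
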