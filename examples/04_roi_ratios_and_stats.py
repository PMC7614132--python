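"""ROI ratio statistics on constructed images: positive-pixel fractions,
crypt/villus and two-channel ratios, proximity ratios, per-subject
aggregation, and a two-group comparison."""

import numpy as np

import organoquant as oq
from organoquant.io import Image2D
from organoquant.quant import RoiSet

# same-channel, two-ROI mode (crypt over villus positive pixels)
px = np.zeros((40, 40), np.uint8)
px[:20, :20] = 200   # crypt: 400 positive pixels
px[20:, :10] = 200   # villus: 200 positive pixels
rois = RoiSet({"crypt": np.zeros((40, 40), bool), "villus": np.zeros((40, 40), bool)})
rois.regions["crypt"][:20] = True
rois.regions["villus"][20:] = True
ratio = oq.roi_positive_ratio(Image2D(px), rois, "crypt", "villus", 100)
print(f"crypt/villus positive-pixel ratio: {ratio.value:.2f}")

# two-channel, one-ROI mode (marker positives over nuclear positives)
marker = Image2D(np.full((20, 20), 150, np.uint8))
dapi = np.zeros((20, 20), np.uint8)
dapi[:, :10] = 200
res = oq.roi_positive_ratio({"psmad2": marker, "dapi": Image2D(dapi)},
                            RoiSet({"crypt": np.ones((20, 20), bool)}),
                            "psmad2", "dapi", {"psmad2": 100, "dapi": 100})
print(f"pSMAD2+/DAPI+ pixel ratio: {res.value:.2f}")

# per-subject aggregation with the minimum-ROI rule (>= 5 crypts per mouse)
values = {f"m1_crypt{i}": 2.0 + 0.1 * i for i in range(6)}
values.update({f"m2_crypt{i}": 1.0 for i in range(3)})
subjects = {k: k.split("_")[0] for k in values}
means, excluded = oq.aggregate_by_subject(values, subjects, min_rois=5)
print(f"per-mouse means: {means}; excluded (too few crypts): {excluded}")

# unpaired two-tailed comparison of two treatment groups
cmp = oq.compare_groups([2.1, 2.4, 2.2, 2.6], [1.2, 1.4, 1.1, 1.5],
                        test="welch_t", groups=("infected", "control"))
print(f"Welch t = {cmp.statistic:.3f}, two-tailed p = {cmp.p_value:.4f}")
# A ratio with a zero-positive denominator is returned flagged undefined,
# never as a silent infinity.
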