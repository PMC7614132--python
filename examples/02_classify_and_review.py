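"""Train the spheroid/budding classifiers on synthetic crops, classify a
fresh scene, and run one round of the manual-correction cycle."""

import numpy as np

import organoquant as oq
from organoquant.io import TrainConfig

# the shape-feature fallback trains in seconds; swap kind="cnn" for the
# convolutional classifier (about a minute on one CPU)
crops, labels = oq.generate_crop_dataset(400, seed=3)
model = oq.train_classifier(list(zip(crops, labels)),
                            TrainConfig(kind="shape_features"), seed=3)
print(f"validation accuracy: {model.metadata['validation_accuracy']:.3f}")

image, truth = oq.generate_brightfield_scene(4, 4, (512, 512), seed=99)
mask = oq.segment_brightfield(image)
records = oq.extract_features(mask, image)
records = oq.classify_organoids(oq.make_crops(image, mask), model, records)
for r in records:
    print(f"  organoid {r.organoid_id}: {r.class_label} (confidence {r.confidence:.2f})")

# manual correction: flip one spheroid call and reject another organoid
sheet = oq.export_review_sheet(records)
flip = sheet.index[sheet.predicted_class == "spheroid"][0]
sheet.loc[flip, "corrected_class"] = "budding"
sheet.loc[sheet.index[-1], "reject"] = "1"
corrected = oq.apply_corrections(records, sheet)
agreement = oq.concordance(records, corrected)
print(f"auto vs corrected agreement: {agreement['agreement']:.2f} "
      f"over {agreement['n']} organoids")
# Corrected records keep the pre-correction label in provenance; rejected
# organoids are excluded from every downstream count and summary.
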