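"""Train a small CNN on phantoms, explain one prediction with Grad-CAM,
and score the explanation with the classification confidence level (CCL).

The CCL is the mean of the strictly positive pixel-wise products of the
normalized Grad-CAM map and the skin layer map: it is high when the
network's evidence sits in diagnostically relevant skin layers and low
when the evidence falls on gel, membrane or deep tissue.
"""

import numpy as np

from usconf import (
    CLASS_NAMES,
    ExperimentConfig,
    RoiSpec,
    build_slm,
    compute_ccl,
    extract_roi,
    generate_dataset,
    gradcam_raw,
    normalize_map,
    train_classifier,
)
from usconf.gradcam import align_map
from usconf.pipeline import standardize_roi
from usconf.types import CLASS_TO_INDEX

cfg = ExperimentConfig(roi_mode=4, max_epochs=10, seed=0)
cohort = generate_dataset(20, 4, seed=0)

inputs, labels, meta = [], [], []
for s in cohort:
    H = build_slm(s.mask, s.image.axial_res)
    roi = extract_roi(s.image, s.mask, H, RoiSpec(cfg.roi_mode))
    inputs.append(standardize_roi(roi.image_roi, cfg.input_size))
    labels.append(CLASS_TO_INDEX[s.label])
    meta.append((H, roi))

inputs, labels = np.array(inputs), np.array(labels)
model, log = train_classifier(inputs[8:], labels[8:], cfg,
                              np.random.default_rng(0))
print(f"training loss: {log[0]:.3f} -> {log[-1]:.3f}")

i = 0  # a held-out sample
logits = model.forward(inputs[i][None, None])
pred = int(np.argmax(logits[0]))
cam = gradcam_raw(model, inputs[i][None], target_class=pred)
L = align_map(normalize_map(cam.raw), cohort[i].image.shape, meta[i][1])
res = compute_ccl(L, meta[i][0])
print(f"true {cohort[i].label}, predicted {CLASS_NAMES[pred]}")
print(f"CCL t = {res.t:.3f} over M = {res.M} relevant salient pixels")
# t near 3 would mean all saliency on the epidermis itself; values around
# 1-2 indicate evidence spread over epidermis plus upper dermis.
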