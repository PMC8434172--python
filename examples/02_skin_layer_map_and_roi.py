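"""Build a skin layer map from an epidermis mask and extract ROI variants.

The skin layer map grades anatomy by diagnostic relevance: 3 on the
epidermis, decreasing through the dermis every 0.5 mm (2, 1, 0.5, 0), 0 in
the gel band directly above, and -1 in avoided regions (membrane, deep
tissue, columns without epidermis). ROI modes 1-4 crop the frame around
the epidermis and zero the avoided pixels.
"""

import numpy as np

from usconf import PhantomSpec, RoiSpec, build_slm, extract_roi, generate_phantom

sample = generate_phantom(PhantomSpec(class_label="psoriasis", seed=4))
H = build_slm(sample.mask, sample.image.axial_res)

values, counts = np.unique(H, return_counts=True)
print("SLM value histogram:")
for v, c in zip(values, counts):
    print(f"  H = {v:4.1f}: {c:6d} px")

for mode in range(5):
    res = extract_roi(sample.image, sample.mask, H, RoiSpec(mode))
    print(f"ROI mode {mode}: rows {res.row_offset}.."
          f"{res.row_offset + res.rows_kept - 1} ({res.rows_kept} kept)")
# Mode 0 keeps the whole frame; modes 1/3 cut 30 px above the epidermis,
# modes 2/4 cut 1 mm above, and modes 3/4 additionally cut 2 mm below it.
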