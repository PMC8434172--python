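"""Region-of-interest extraction around the segmented epidermis.

Five rectangular cropping variants standardize the vertical placement of
skin layers before classification:

====  ==================================================================
 0    no crop, no zeroing (original image passthrough)
 1    remove rows above (epidermis top row − 30 px)
 2    remove rows above (epidermis top row − 1 mm)
 3    as 1, plus remove rows below (epidermis bottom row + 2 mm)
 4    as 2, plus remove rows below (epidermis bottom row + 2 mm)
====  ==================================================================

"Top"/"bottom" are the global min/max epidermis rows over all columns
(crops are rectangular). mm margins convert to rows through the axial
resolution only, rounded to nearest. In modes 1–4 every retained pixel
marked avoided (−1) in the skin layer map is set to zero, so probe
membrane, residual gel and muscle cannot feed the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import EpidermisMask, UltrasoundImage, require_same_shape

logger = logging.getLogger(__name__)

UPPER_MARGIN_PX = 30    # modes 1, 3
UPPER_MARGIN_MM = 1.0   # modes 2, 4
LOWER_MARGIN_MM = 2.0   # modes 3, 4


@dataclass(frozen=True)
class RoiSpec:
    """Cropping variant selector; see the module docstring for the modes."""

    mode: int

    def __post_init__(self) -> None:
        if self.mode not in (0, 1, 2, 3, 4):
            raise ValueError(f"ROI mode must be 0..4, got {self.mode}")

    @property
    def zero_avoided(self) -> bool:
        return self.mode != 0

    @property
    def crops_bottom(self) -> bool:
        return self.mode in (3, 4)


@dataclass
class RoiResult:
    """A cropped image strip and where it sat in the original frame."""

    image_roi: np.ndarray
    row_offset: int
    rows_kept: int


def extract_roi(
    image: UltrasoundImage,
    mask: EpidermisMask,
    slm: np.ndarray | None,
    spec: RoiSpec,
) -> RoiResult:
    """Crop ``image`` around the epidermis and zero avoided pixels.

    ``slm`` is required for modes 1–4 (its −1 labels are the single source
    of truth for the avoided regions); ignored in mode 0. Crop bounds that
    fall outside the image are clamped (and logged).
    """
    px = image.pixels
    if spec.mode == 0:
        return RoiResult(px.copy(), 0, px.shape[0])

    require_same_shape(px, mask.grid, "image/mask")
    if mask.is_empty:
        raise ValueError("cannot extract an ROI from an empty epidermis mask")
    if slm is None:
        raise ValueError("modes 1-4 need the skin layer map for avoided-pixel zeroing")
    require_same_shape(px, slm, "image/SLM")

    top = mask.top_row()
    if spec.mode in (1, 3):
        margin_px = UPPER_MARGIN_PX
    else:
        margin_px = int(round(UPPER_MARGIN_MM / image.axial_res))
    first = top - margin_px

    if spec.crops_bottom:
        bottom = mask.bottom_row()
        last = bottom + int(round(LOWER_MARGIN_MM / image.axial_res))
    else:
        last = px.shape[0] - 1

    clamped_first = max(first, 0)
    clamped_last = min(last, px.shape[0] - 1)
    if clamped_first != first or clamped_last != last:
        logger.info(
            "ROI bounds clamped to the image: rows %d..%d -> %d..%d",
            first, last, clamped_first, clamped_last,
        )

    strip = px[clamped_first: clamped_last + 1].copy()
    strip[slm[clamped_first: clamped_last + 1] == -1.0] = 0.0
    return RoiResult(strip, clamped_first, strip.shape[0])
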