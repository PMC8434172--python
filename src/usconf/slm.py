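"""Skin layer map (SLM) construction.

The SLM grades every pixel of an HFUS frame by its anatomical relevance to
skin diagnosis, anchored on the segmented epidermis. Values:

====  =====================================================================
 3    epidermis (the segmentation mask itself)
 2    first 0.5 mm of dermis below the epidermis
 1    0.5–1.0 mm below
 0.5  1.0–1.5 mm below
 0    1.5–2.0 mm below, and the gel band directly above the epidermis
−1    avoided regions: probe membrane, remaining gel, muscle, and any
      column without epidermis
====  =====================================================================

Relevance therefore decreases twice by 1 per 0.5 mm of depth, then twice
by 0.5 per 0.5 mm until the ~2 mm dermis ends. Depth is measured per
column from that column's own epidermis boundary (skin layers run roughly
parallel to the epidermis), on pixel-center coordinates:
row ``r`` sits ``(r - boundary_row) * axial_res`` mm below the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .types import EpidermisMask

#: Allowed SLM values.
SLM_VALUES = (-1.0, 0.0, 0.5, 1.0, 2.0, 3.0)

# (depth_lo_mm, depth_hi_mm] -> value, below the column's lowest epidermis px
_DERMIS_BANDS = ((0.0, 0.5, 2.0), (0.5, 1.0, 1.0), (1.0, 1.5, 0.5), (1.5, 2.0, 0.0))


def build_slm(mask: EpidermisMask, axial_res: float, gel_band_px: int = 30) -> np.ndarray:
    """Build the skin layer map ``H`` for one frame.

    Parameters
    ----------
    mask:
        Non-empty binary epidermis mask.
    axial_res:
        Axial pixel size in mm/pixel (converts depth bands to rows).
    gel_band_px:
        Rows of ultrasound gel directly above the epidermis that are kept
        (value 0) rather than avoided.

    Returns
    -------
    Float array with values in ``{-1, 0, 0.5, 1, 2, 3}``, same grid as the
    mask. Columns containing no epidermis are −1 throughout.
    """
    if mask.is_empty:
        raise ValueError("cannot build a skin layer map from an empty mask")
    if axial_res <= 0:
        raise ValueError("axial resolution must be positive")

    grid = mask.grid
    h, w = grid.shape
    H = np.full((h, w), -1.0)

    has_epi = grid.any(axis=0)
    rows = np.arange(h)[:, None]

    # Per-column highest/lowest epidermis rows (argmax finds first True).
    top = grid.argmax(axis=0)
    bottom = h - 1 - grid[::-1].argmax(axis=0)

    # Depth below the column's lowest epidermis pixel, in mm.
    # eps guards band edges against float rounding of axial_res multiples,
    # so a pixel exactly on a 0.5 mm boundary lands in the shallower band.
    eps = 1e-9
    depth = (rows - bottom[None, :]) * axial_res
    for lo, hi, value in _DERMIS_BANDS:
        sel = (depth > lo + eps) & (depth <= hi + eps)
        H[sel] = value

    # Gel band: gel_band_px rows immediately above the column's top pixel.
    gel = (rows >= top[None, :] - gel_band_px) & (rows < top[None, :])
    H[gel] = 0.0

    # Pixels inside the epidermis span but off the mask keep the first
    # dermis grade; the mask itself is exactly 3.
    within = (rows >= top[None, :]) & (rows <= bottom[None, :]) & ~grid
    H[within] = 2.0
    H[grid] = 3.0

    H[:, ~has_epi] = -1.0
    return H


def save_slm(H: np.ndarray, path: str | Path) -> None:
    """Persist as single-channel float32 TIFF."""
    tifffile.imwrite(Path(path), H.astype(np.float32))


def load_slm(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def save_slm_preview(H: np.ndarray, path: str | Path) -> None:
    """Colormapped PNG preview (viridis over the value range)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(H, cmap="viridis", vmin=-1, vmax=3)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(Path(path), dpi=100, bbox_inches="tight")
    plt.close(fig)
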