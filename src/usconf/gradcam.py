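"""Grad-CAM saliency maps.

For a classifier with final-convolutional feature maps :math:`A^k` and
pre-softmax class score :math:`y^c`, the map is

.. math::

    L^c = \\mathrm{ReLU}\\Big(\\sum_k \\alpha_k^c A^k\\Big),
    \\qquad
    \\alpha_k^c = \\frac{1}{Z} \\sum_{i,j}
        \\frac{\\partial y^c}{\\partial A^k_{ij}},

with :math:`Z` the number of spatial positions of the feature map. The
target class ``c`` defaults to the model's own prediction. The raw map is
min–max normalized per image to [0, 1] (an all-constant map — no localized
evidence — normalizes to all zeros), bilinearly rescaled to the ROI grid,
and placed back on the original image canvas so it aligns pixel-for-pixel
with the skin layer map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import Sequential
from .roi import RoiResult


@dataclass
class GradCamMap:
    """Raw (feature-map-resolution) and processed states of one map."""

    raw: np.ndarray
    target_class: int
    layer_id: int
    normalized: np.ndarray | None = None


def gradcam_raw(
    model: Sequential,
    image_input: np.ndarray,
    target_class: int | None = None,
    layer_id: int | None = None,
) -> GradCamMap:
    """Compute the unnormalized Grad-CAM map for one input.

    Parameters
    ----------
    model:
        A :class:`~usconf.nn.Sequential` whose output is class logits.
    image_input:
        Array of shape (C, H, W) or (1, C, H, W) — a single sample.
    target_class:
        Class whose score is explained; defaults to the predicted class.
    layer_id:
        Index of the layer whose output activations serve as the feature
        maps; defaults to the last layer with spatial extent.
    """
    x = np.asarray(image_input, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError("gradcam_raw explains a single sample")

    logits = model.forward(x)
    if target_class is None:
        target_class = int(np.argmax(logits[0]))
    if layer_id is None:
        layer_id = model.last_spatial_index()
    if not model.layers[layer_id].spatial:
        raise ValueError(f"layer {layer_id} has no spatial activations")

    A = model.activations[layer_id + 1]          # (1, K, h, w)
    if A.ndim != 4:
        raise ValueError(f"layer {layer_id} output is not a feature-map stack")

    seed = np.zeros_like(logits)
    seed[0, target_class] = 1.0                   # d y_c / d logits
    dA = model.grad_wrt_activation(layer_id, seed)  # (1, K, h, w)

    Z = A.shape[2] * A.shape[3]
    alpha = dA[0].sum(axis=(1, 2)) / Z            # (K,)
    raw = np.maximum((alpha[:, None, None] * A[0]).sum(axis=0), 0.0)
    return GradCamMap(raw=raw, target_class=target_class, layer_id=layer_id)


def normalize_map(raw: np.ndarray) -> np.ndarray:
    """Per-image min–max normalization to [0, 1]; constant maps become 0."""
    raw = np.asarray(raw, dtype=np.float64)
    if (raw < 0).any():
        raise ValueError("raw Grad-CAM maps are non-negative by construction")
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def align_map(
    normalized: np.ndarray,
    original_size: tuple[int, int],
    roi: RoiResult | None = None,
) -> np.ndarray:
    """Rescale a normalized map to the ROI grid and embed it in the frame.

    Bilinear upsampling to ``(roi.rows_kept, original width)``, then
    placement at ``roi.row_offset`` within a zero canvas of
    ``original_size``; zeros outside the ROI mean those pixels can never
    enter the confidence average. With ``roi=None`` the map is rescaled to
    the full frame.
    """
    h, w = original_size
    if roi is None:
        return resize(normalized, (h, w), order=1, mode="edge", anti_aliasing=False)
    if roi.row_offset < 0 or roi.row_offset + roi.rows_kept > h:
        raise ValueError("ROI offsets are inconsistent with the original size")
    strip = resize(normalized, (roi.rows_kept, w), order=1, mode="edge",
                   anti_aliasing=False)
    canvas = np.zeros((h, w))
    canvas[roi.row_offset: roi.row_offset + roi.rows_kept] = strip
    return canvas
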