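"""Classification confidence level (CCL).

The CCL scores how much of a classifier's Grad-CAM evidence falls inside
diagnostically relevant anatomy. With ``L`` the per-image-normalized
Grad-CAM map and ``H`` the skin layer map on the same grid, the confidence
map collects the strictly positive pixel-wise products

.. math::  G = \\{\\, L(i,j)\\,H(i,j) : L(i,j)\\,H(i,j) > 0 \\,\\}

and the scalar confidence level is their mean,
:math:`t = \\frac{1}{M}\\sum G`, with :math:`M = |G|`. Pixels in avoided
or gel regions (``H <= 0``) and pixels without saliency (``L = 0``) never
contribute. ``t`` ranges from 0 (no evidence inside relevant skin layers)
to 3 (all evidence concentrated on the epidermis). The empty case
``M = 0`` is defined as ``t = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import require_same_shape


@dataclass
class ConfidenceMap:
    products: np.ndarray   # element-wise L*H
    included: np.ndarray   # products strictly > 0
    M: int


@dataclass
class CCLResult:
    t: float
    M: int
    model_id: str = ""
    sample_id: str = ""


def confidence_map(L_norm: np.ndarray, H: np.ndarray) -> ConfidenceMap:
    """Element-wise product of saliency and anatomy, with inclusion set."""
    L = np.asarray(L_norm, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    require_same_shape(L, H, "Grad-CAM map/SLM")
    if L.min() < 0 or L.max() > 1:
        raise ValueError("normalized Grad-CAM map must lie in [0, 1]")
    products = L * H
    included = products > 0
    return ConfidenceMap(products=products, included=included, M=int(included.sum()))


def ccl(cmap: ConfidenceMap, model_id: str = "", sample_id: str = "") -> CCLResult:
    """Mean of the included products; ``M = 0`` maps to ``t = 0``."""
    if cmap.M == 0:
        return CCLResult(t=0.0, M=0, model_id=model_id, sample_id=sample_id)
    t = float(cmap.products[cmap.included].mean())
    return CCLResult(t=t, M=cmap.M, model_id=model_id, sample_id=sample_id)


def compute_ccl(L_norm: np.ndarray, H: np.ndarray,
                model_id: str = "", sample_id: str = "") -> CCLResult:
    """Convenience one-shot: :func:`confidence_map` then :func:`ccl`."""
    return ccl(confidence_map(L_norm, H), model_id=model_id, sample_id=sample_id)
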