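"""Core containers for high-frequency ultrasound (HFUS) skin image analysis.

Images are stored as float arrays in [0, 1] with explicit physical pixel
resolutions (mm/pixel), because every depth-dependent operation in this
package (skin layer maps, ROI margins) works in millimetres and converts
to rows through the axial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Fixed class order used everywhere (confusion matrices, softmax heads).
CLASS_NAMES = ("AD", "psoriasis", "tumor", "control")
CLASS_TO_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class UltrasoundImage:
    """A grayscale HFUS frame with its acquisition geometry.

    Parameters
    ----------
    pixels:
        2-D float array, rows = axial depth (top of image = shallow),
        columns = lateral position. Values in [0, 1].
    lateral_res, axial_res:
        Physical pixel size in mm/pixel along columns and rows.
    label:
        Optional class name from :data:`CLASS_NAMES`.
    patient_id:
        Optional patient identifier; drives patient-wise cross-validation.
    """

    pixels: np.ndarray
    lateral_res: float
    axial_res: float
    label: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("image must be a 2-D grayscale array")
        if self.axial_res <= 0 or self.lateral_res <= 0:
            raise ValueError("pixel resolutions must be positive (mm/pixel)")
        if self.label is not None and self.label not in CLASS_TO_INDEX:
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save_png(self, path: str | Path) -> None:
        """Write as 16-bit grayscale PNG."""
        arr = np.clip(self.pixels, 0.0, 1.0)
        iio.imwrite(Path(path), (arr * 65535.0 + 0.5).astype(np.uint16))

    @classmethod
    def load_png(
        cls,
        path: str | Path,
        lateral_res: float,
        axial_res: float,
        label: str | None = None,
        patient_id: str | None = None,
    ) -> "UltrasoundImage":
        raw = np.asarray(iio.imread(Path(path)))
        if raw.ndim == 3:  # collapse accidental RGB
            raw = raw.mean(axis=2)
        if np.issubdtype(raw.dtype, np.integer):
            arr = raw.astype(np.float64) / np.iinfo(raw.dtype).max
        else:
            arr = raw.astype(np.float64)
        return cls(arr, lateral_res, axial_res, label=label, patient_id=patient_id)


@dataclass
class EpidermisMask:
    """Binary epidermis mask aligned to an :class:`UltrasoundImage` grid."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("mask must be a 2-D binary array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def top_row(self) -> int:
        """Global minimum epidermis row over all columns."""
        rows = np.flatnonzero(self.grid.any(axis=1))
        if rows.size == 0:
            raise ValueError("mask is empty")
        return int(rows[0])

    def bottom_row(self) -> int:
        """Global maximum epidermis row over all columns."""
        rows = np.flatnonzero(self.grid.any(axis=1))
        if rows.size == 0:
            raise ValueError("mask is empty")
        return int(rows[-1])

    def save_png(self, path: str | Path) -> None:
        iio.imwrite(Path(path), (self.grid.astype(np.uint8) * 255))

    @classmethod
    def load_png(cls, path: str | Path) -> "EpidermisMask":
        arr = np.asarray(iio.imread(Path(path)))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return cls(arr > (arr.max() / 2 if arr.max() > 1 else 0))


def require_same_shape(a: np.ndarray, b: np.ndarray, what: str = "grids") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} differ in shape: {a.shape} vs {b.shape}")
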