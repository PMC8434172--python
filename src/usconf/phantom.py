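"""Synthetic HFUS skin phantoms.

Generates desk-scale grayscale frames that mimic the layered appearance of
high-frequency ultrasound skin scans: a bright probe-membrane line at the
top, a dark ultrasound-gel zone, a bright, gently undulating epidermis band,
an optional dark subepidermal low-echogenic band (SLEB, the hallmark of
inflammatory disease), a speckled dermis with an optional hypoechoic tumor
disk, and a deep muscle zone. Every phantom carries a pixel-exact ground
truth epidermis mask, a class label, and a patient identifier, so the whole
segmentation/ROI/saliency/confidence pipeline is testable without any
external data.

Four classes are produced:

``AD``
    atopic dermatitis — a SLEB of the specified thickness under the epidermis;
``psoriasis``
    thickened epidermis (x1.8 by default) plus a thinner SLEB;
``tumor``
    a hypoechoic disk inside the dermis;
``control``
    none of the above.

The generator is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .types import CLASS_NAMES, EpidermisMask, UltrasoundImage

# Region codes of the internal label drawing (noiseless geometry).
REGION_BACKGROUND = 0
REGION_MEMBRANE = 1
REGION_GEL = 2
REGION_EPIDERMIS = 3
REGION_SLEB = 4
REGION_DERMIS = 5
REGION_TUMOR = 6
REGION_MUSCLE = 7

#: Mean echo intensity of each region, ordered membrane > epidermis >
#: dermis > muscle > SLEB >= gel so the band structure survives speckle.
DEFAULT_INTENSITIES = {
    REGION_BACKGROUND: 0.02,
    REGION_MEMBRANE: 0.95,
    REGION_GEL: 0.05,
    REGION_EPIDERMIS: 0.80,
    REGION_SLEB: 0.12,
    REGION_DERMIS: 0.45,
    REGION_TUMOR: 0.10,
    REGION_MUSCLE: 0.30,
}

PSORIASIS_EPIDERMIS_FACTOR = 1.8  # epidermis thickening in psoriasis
PSORIASIS_SLEB_FACTOR = 0.5      # psoriasis SLEB is thinner than AD's


@dataclass
class PhantomSpec:
    """Geometry and appearance of a single synthetic frame.

    Depths are in mm measured from the top of the image; the axial (row)
    resolution converts them to pixel rows. Defaults describe a 256x256
    frame at 0.02 mm/px axially, so the epidermis plus the 2 mm skin-layer
    band structure spans roughly half of the frame.
    """

    class_label: str = "control"
    height_px: int = 256
    width_px: int = 256
    lateral_res: float = 0.02
    axial_res: float = 0.02
    epidermis_top_mm: float = 1.2
    epidermis_thickness_mm: float = 0.30
    sleb_thickness_mm: float = 0.40          # used by AD; halved for psoriasis
    tumor_center_mm: float = 2.6             # depth of tumor center
    tumor_radius_mm: float = 0.6
    muscle_top_mm: float = 4.3
    membrane_rows: int = 3
    undulation_amp_mm: float = 0.08          # sinusoidal epidermis top boundary
    undulation_periods: float = 1.5
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    speckle_scale: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.axial_res <= 0 or self.lateral_res <= 0:
            raise ValueError("resolutions must be positive")
        if self.sleb_thickness_mm < 0:
            raise ValueError("SLEB thickness must be >= 0")
        depth_mm = self.height_px * self.axial_res
        thick = self.epidermis_thickness_mm
        if self.class_label == "psoriasis":
            thick *= PSORIASIS_EPIDERMIS_FACTOR
        needed = (self.epidermis_top_mm + self.undulation_amp_mm + thick + 2.0)
        if needed > depth_mm:
            raise ValueError(
                f"geometry does not fit the grid: epidermis top + thickness "
                f"+ 2 mm = {needed:.2f} mm exceeds image depth {depth_mm:.2f} mm"
            )
        if self.class_label == "tumor":
            lo = self.tumor_center_mm - self.tumor_radius_mm
            hi = self.tumor_center_mm + self.tumor_radius_mm
            if lo < self.epidermis_top_mm + thick or hi > depth_mm:
                raise ValueError("tumor disk does not fit inside the dermis")


@dataclass
class PhantomSample:
    """A generated frame with its ground truth."""

    image: UltrasoundImage
    mask: EpidermisMask
    label: str
    patient_id: str
    region_map: np.ndarray  # noiseless geometry drawing (region codes)


def _region_map(spec: PhantomSpec) -> np.ndarray:
    """Draw the noiseless region-code map, top to bottom per column."""
    h, w, ares = spec.height_px, spec.width_px, spec.axial_res
    regions = np.full((h, w), REGION_BACKGROUND, dtype=np.int8)
    rows = np.arange(h)[:, None]

    # Undulating epidermis top boundary (row index per column).
    cols = np.arange(w)
    wave = np.sin(2 * np.pi * spec.undulation_periods * cols / max(w, 1))
    top_row = np.rint(
        spec.epidermis_top_mm / ares + (spec.undulation_amp_mm / ares) * wave
    ).astype(int)

    epi_mm = spec.epidermis_thickness_mm
    sleb_mm = 0.0
    if spec.class_label == "AD":
        sleb_mm = spec.sleb_thickness_mm
    elif spec.class_label == "psoriasis":
        epi_mm *= PSORIASIS_EPIDERMIS_FACTOR
        sleb_mm = spec.sleb_thickness_mm * PSORIASIS_SLEB_FACTOR

    n_epi = max(int(round(epi_mm / ares)), 1)
    n_sleb = int(round(sleb_mm / ares))
    bot_row = top_row + n_epi - 1            # inclusive epidermis bottom
    sleb_end = bot_row + n_sleb              # inclusive SLEB bottom
    muscle_row = int(round(spec.muscle_top_mm / ares))

    regions[rows < top_row] = REGION_GEL
    regions[(rows >= top_row) & (rows <= bot_row)] = REGION_EPIDERMIS
    if n_sleb > 0:
        regions[(rows > bot_row) & (rows <= sleb_end)] = REGION_SLEB
    regions[rows > sleb_end] = REGION_DERMIS
    if muscle_row < h:
        deep = (rows >= muscle_row) & (rows > sleb_end)
        regions[deep] = REGION_MUSCLE
    regions[: spec.membrane_rows, :] = REGION_MEMBRANE

    if spec.class_label == "tumor":
        cy = spec.tumor_center_mm / ares
        cx = w / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        rr = ((yy - cy) * ares) ** 2 + ((xx - cx) * spec.lateral_res) ** 2
        disk = rr <= spec.tumor_radius_mm**2
        regions[disk & (regions == REGION_DERMIS)] = REGION_TUMOR
    return regions


def generate_phantom(spec: PhantomSpec, patient_id: str = "P000") -> PhantomSample:
    """Render one phantom: geometry drawing, intensities, speckle.

    Deterministic for a fixed ``spec.seed``. Raises ``ValueError`` when the
    requested geometry does not fit the grid.
    """
    spec.validate()
    regions = _region_map(spec)
    img = np.empty(regions.shape, dtype=np.float64)
    for code, level in spec.intensities.items():
        img[regions == code] = level

    if spec.speckle_scale > 0:
        rng = np.random.default_rng(spec.seed)
        # Multiplicative Rayleigh speckle, normalized to unit mean; the
        # scale blends it in so the band ordering survives.
        ray = rng.rayleigh(scale=1.0, size=img.shape) / np.sqrt(np.pi / 2.0)
        img = img * (1.0 + spec.speckle_scale * (ray - 1.0))
    img = np.clip(img, 0.0, 1.0)

    image = UltrasoundImage(
        img, spec.lateral_res, spec.axial_res,
        label=spec.class_label, patient_id=patient_id,
    )
    mask = EpidermisMask(regions == REGION_EPIDERMIS)
    return PhantomSample(image, mask, spec.class_label, patient_id, regions)


def generate_dataset(
    n_per_class: int,
    n_patients_per_class: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomSample]:
    """Generate a labelled multi-patient phantom cohort.

    Images are dealt to patients round-robin so some patients own several
    images (required for meaningful patient-wise cross-validation). Each
    patient gets a persistent random offset on epidermis depth/thickness so
    their images correlate, plus small per-image jitter.
    """
    if n_per_class < n_patients_per_class or n_patients_per_class < 1:
        raise ValueError("need n_per_class >= n_patients_per_class >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for ci, cls in enumerate(CLASS_NAMES):
        offsets = {
            p: (rng.uniform(-0.15, 0.15), rng.uniform(-0.04, 0.04), rng.uniform(-0.06, 0.06))
            for p in range(n_patients_per_class)
        }
        for i in range(n_per_class):
            p = i % n_patients_per_class
            d_top, d_thick, d_sleb = offsets[p]
            spec = replace(
                base,
                class_label=cls,
                epidermis_top_mm=base.epidermis_top_mm + d_top + rng.uniform(-0.05, 0.05),
                epidermis_thickness_mm=max(
                    base.epidermis_thickness_mm + d_thick + rng.uniform(-0.02, 0.02), 0.1
                ),
                sleb_thickness_mm=max(
                    base.sleb_thickness_mm + d_sleb + rng.uniform(-0.03, 0.03), 0.15
                ),
                undulation_periods=base.undulation_periods + rng.uniform(-0.5, 0.5),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            patient = f"{cls}_pat{p:02d}"
            samples.append(generate_phantom(spec, patient_id=patient))
    return samples


def write_dataset(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Persist images (16-bit PNG), masks (binary PNG) and a CSV manifest.

    Returns the manifest path. Manifest columns:
    ``file,mask,label,patient_id,lateral_res_mm,axial_res_mm``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["file", "mask", "label", "patient_id", "lateral_res_mm", "axial_res_mm"])
        for i, s in enumerate(samples):
            img_rel = f"images/{i:04d}_{s.label}.png"
            msk_rel = f"masks/{i:04d}_{s.label}.png"
            s.image.save_png(out / img_rel)
            s.mask.save_png(out / msk_rel)
            wr.writerow(
                [img_rel, msk_rel, s.label, s.patient_id,
                 s.image.lateral_res, s.image.axial_res]
            )
    return manifest
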