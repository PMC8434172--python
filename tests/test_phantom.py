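import dataclasses

import numpy as np
import pytest

from usconf.phantom import (
    REGION_DERMIS,
    REGION_EPIDERMIS,
    REGION_SLEB,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
    write_dataset,
)


def test_noiseless_intensity_ordering():
    """Membrane > epidermis > dermis > SLEB >= gel on the clean image."""
    s = generate_phantom(PhantomSpec(class_label="AD", speckle_scale=0.0))
    img, reg = s.image.pixels, s.region_map

    def mean_of(code):
        return img[reg == code].mean()

    from usconf.phantom import REGION_GEL, REGION_MEMBRANE

    assert (mean_of(REGION_MEMBRANE) > mean_of(REGION_EPIDERMIS)
            > mean_of(REGION_DERMIS) > mean_of(REGION_SLEB)
            >= mean_of(REGION_GEL))


def test_same_seed_bit_identical():
    spec = PhantomSpec(class_label="tumor", seed=7)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    np.testing.assert_array_equal(a.image.pixels, b.image.pixels)
    np.testing.assert_array_equal(a.mask.grid, b.mask.grid)


def test_sleb_row_count_matches_independent_geometry():
    """AD with 0.5 mm SLEB at 0.05 mm/px axial: the region map must show
    exactly round(0.5/0.05) = 10 SLEB rows below the epidermis in every
    column (independent mm->px arithmetic)."""
    spec = PhantomSpec(
        class_label="AD", sleb_thickness_mm=0.5, axial_res=0.05,
        height_px=100, width_px=40, epidermis_top_mm=1.0,
        muscle_top_mm=4.5, speckle_scale=0.0,
    )
    s = generate_phantom(spec)
    expected_rows = round(spec.sleb_thickness_mm / spec.axial_res)
    per_column = (s.region_map == REGION_SLEB).sum(axis=0)
    assert (per_column == expected_rows).all()
    # SLEB sits directly below the lowest epidermis pixel of each column
    for col in range(spec.width_px):
        epi = np.flatnonzero(s.region_map[:, col] == REGION_EPIDERMIS)
        sleb = np.flatnonzero(s.region_map[:, col] == REGION_SLEB)
        assert sleb[0] == epi[-1] + 1


def test_mask_equals_epidermis_region():
    for cls in ("AD", "psoriasis", "tumor", "control"):
        s = generate_phantom(PhantomSpec(class_label=cls, seed=3))
        np.testing.assert_array_equal(s.mask.grid,
                                      s.region_map == REGION_EPIDERMIS)
        assert s.mask.grid.any()
        assert s.mask.shape == s.image.shape


def test_geometry_that_does_not_fit_is_rejected():
    bad = PhantomSpec(height_px=64, axial_res=0.02)  # 1.28 mm depth
    with pytest.raises(ValueError, match="does not fit"):
        generate_phantom(bad)


def test_dataset_counts_patients_and_determinism(tmp_path):
    samples = generate_dataset(10, 3, seed=11)
    assert len(samples) == 40
    labels = [s.label for s in samples]
    for cls in ("AD", "psoriasis", "tumor", "control"):
        assert labels.count(cls) == 10
        patients = {s.patient_id for s in samples if s.label == cls}
        assert len(patients) == 3  # some patients own several images

    again = generate_dataset(10, 3, seed=11)
    for a, b in zip(samples, again):
        assert a.patient_id == b.patient_id
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    manifest = write_dataset(samples[:4], tmp_path)
    text = manifest.read_text()
    assert text.splitlines()[0] == "file,mask,label,patient_id,lateral_res_mm,axial_res_mm"
    assert len(text.splitlines()) == 5


def test_shared_patient_when_counts_force_it():
    samples = generate_dataset(2, 1, seed=0)
    for cls in ("AD", "control"):
        ids = [s.patient_id for s in samples if s.label == cls]
        assert len(set(ids)) == 1


def test_ad_control_separable_by_subepidermal_intensity():
    """Mean intensity in the 1 mm band below the epidermis separates AD
    (dark SLEB) from control at >= 95% with a single threshold, at the
    default speckle level (100 phantoms)."""
    rng = np.random.default_rng(42)
    feats, is_ad = [], []
    for i in range(100):
        cls = "AD" if i % 2 == 0 else "control"
        spec = PhantomSpec(class_label=cls, seed=int(rng.integers(2**31)))
        s = generate_phantom(spec)
        band_px = round(1.0 / spec.axial_res)
        vals = []
        for col in range(0, spec.width_px, 8):
            epi = np.flatnonzero(s.mask.grid[:, col])
            vals.append(s.image.pixels[epi[-1] + 1: epi[-1] + 1 + band_px, col].mean())
        feats.append(np.mean(vals))
        is_ad.append(cls == "AD")
    feats, is_ad = np.array(feats), np.array(is_ad)
    thresholds = np.linspace(feats.min(), feats.max(), 200)
    best = max(((feats < t) == is_ad).mean() for t in thresholds)
    assert best >= 0.95
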