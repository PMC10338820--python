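"""Phantom generation, degradation and dataset contracts."""

import numpy as np
import pytest

from cbctcx.image_io import to_unit_range
from cbctcx.metrics import psnr
from cbctcx.phantom import (ArtifactSpec, Nodule, PhantomSpec, cup_field,
                            dataset_hash, degrade, elastic_warp, generate_clean,
                            load_dataset, make_dataset, roi_masks)


def test_generation_is_deterministic(tiny_phantom_spec):
    a = generate_clean(tiny_phantom_spec, 42)
    b = generate_clean(tiny_phantom_spec, 42)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    c = generate_clean(tiny_phantom_spec, 43)
    assert (a.pixels != c.pixels).any()


def test_zero_jitter_classes_render_at_exact_means():
    spec = PhantomSpec(size=64, intensity_jitter=0.0, geom_jitter=0.0, nodules=())
    img = generate_clean(spec, 0)
    masks = roi_masks(spec, 0)
    assert set(np.unique(img.pixels)) <= {0, int(spec.lung_intensity),
                                          int(spec.soft_intensity),
                                          int(spec.skin_intensity),
                                          int(spec.bone_intensity)}
    # spine disk mean equals the configured bone level, via an independent mask-mean
    vals = img.pixels[masks["bone"]]
    assert float(vals.mean()) == spec.bone_intensity


def test_jittered_class_means_stay_within_bounds(tiny_phantom_spec):
    spec = tiny_phantom_spec
    for seed in (0, 1, 2):
        img = generate_clean(spec, seed)
        bone = img.pixels[roi_masks(spec, seed)["bone"]].astype(float).mean()
        assert abs(bone - spec.bone_intensity) <= spec.intensity_jitter + 0.5


def test_spec_validation_rejects_out_of_image_geometry():
    with pytest.raises(ValueError, match="body ellipse"):
        PhantomSpec(body_axes=(0.99, 0.99), geom_jitter=0.05)
    with pytest.raises(ValueError, match="ordered"):
        PhantomSpec(lung_intensity=300.0, soft_intensity=250.0)


def test_zero_amplitude_degradation_is_identity(tiny_phantom_spec):
    img = generate_clean(tiny_phantom_spec, 5)
    art = ArtifactSpec(cup_amplitude=0, shadow_amplitude=0, streak_count=0,
                       noise_sigma=0, deform_amplitude=0)
    out = degrade(img, art, 99)
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_cup_only_degradation_matches_closed_form_bias():
    spec = PhantomSpec(size=32, intensity_jitter=0.0, geom_jitter=0.0, nodules=(),
                       rib_count=0)
    img = generate_clean(spec, 0)
    art = ArtifactSpec(cup_amplitude=0.2, cup_exponent=2.0, shadow_amplitude=0,
                       streak_count=0, noise_sigma=0)
    out = degrade(img, art, 0)
    # closed form: 1 - a*(1 - r^p) with r over pixel-center coordinates
    c = (np.arange(32) + 0.5) / 32 * 2 - 1
    yy, xx = np.meshgrid(c, c, indexing="ij")
    r = np.minimum(np.hypot(yy, xx), 1.0)
    field = 1 - 0.2 * (1 - r ** 2)
    expected = np.clip(np.floor(img.pixels * field + 0.5), 0, 511)
    np.testing.assert_array_equal(out.pixels, expected)
    # radially monotone: depression is strongest at the center
    center_f, rim_f = field[16, 16], field[16, 1]
    assert center_f < rim_f


def test_cup_field_endpoints():
    f = cup_field(64, amplitude=0.3, exponent=2.0)
    assert f.min() >= 0.7 - 1e-12 and f.max() <= 1.0 + 1e-12


def test_degradation_strictly_lowers_fidelity(tiny_phantom_spec):
    img = generate_clean(tiny_phantom_spec, 11)
    degraded = degrade(img, ArtifactSpec(), 3)
    tiny_noise = degrade(img, ArtifactSpec(cup_amplitude=0, shadow_amplitude=0,
                                           streak_count=0, noise_sigma=0.6), 3)
    assert psnr(img, degraded) < psnr(img, tiny_noise)


def test_degradation_stays_in_range(tiny_phantom_spec):
    art = ArtifactSpec(streak_amplitude=400.0, noise_sigma=80.0)
    out = degrade(generate_clean(tiny_phantom_spec, 1), art, 1)
    assert out.pixels.min() >= 0 and out.pixels.max() <= 511


def test_elastic_warp_deforms_but_preserves_range(tiny_phantom_spec):
    img = generate_clean(tiny_phantom_spec, 7)
    warped = elastic_warp(img, 2.0, 5)
    assert (warped.pixels != img.pixels).any()
    assert warped.pixels.max() <= 511
    np.testing.assert_array_equal(elastic_warp(img, 0.0, 5).pixels, img.pixels)


def test_dataset_counts_and_unpairedness(tiny_phantom_spec):
    ds = make_dataset(4, 2, tiny_phantom_spec, ArtifactSpec(), 21)
    assert len(ds.train_cbct) == len(ds.train_ct) == 4
    assert len(ds.test_cbct) == len(ds.test_ct) == 2
    rows = {(r["split"], r["domain"]): [] for r in ds.manifest}
    for r in ds.manifest:
        rows[(r["split"], r["domain"])].append(r["anatomy_seed"])
    # unpaired training: zero anatomy-seed overlap between domains
    assert not set(rows[("train", "cbct")]) & set(rows[("train", "ct")])
    # paired test split: identical anatomy seeds in both domains
    assert rows[("test", "cbct")] == rows[("test", "ct")]


def test_dataset_regeneration_is_byte_identical(tiny_phantom_spec, tmp_path):
    art = ArtifactSpec()
    a = make_dataset(3, 2, tiny_phantom_spec, art, 77, out_dir=tmp_path / "a")
    b = make_dataset(3, 2, tiny_phantom_spec, art, 77, out_dir=tmp_path / "b")
    assert dataset_hash(a) == dataset_hash(b)
    for row in a.manifest:
        fa = (tmp_path / "a" / row["filename"]).read_bytes()
        fb = (tmp_path / "b" / row["filename"]).read_bytes()
        assert fa == fb
    # and a different master seed changes the content
    c = make_dataset(3, 2, tiny_phantom_spec, art, 78)
    assert dataset_hash(c) != dataset_hash(a)


def test_dataset_round_trips_through_manifest(tiny_phantom_spec, tmp_path):
    ds = make_dataset(2, 2, tiny_phantom_spec, ArtifactSpec(), 5, out_dir=tmp_path)
    loaded = load_dataset(tmp_path)
    for attr in ("train_cbct", "train_ct", "test_cbct", "test_ct"):
        for orig, back in zip(getattr(ds, attr), getattr(loaded, attr)):
            np.testing.assert_array_equal(orig.pixels, back.pixels)


def test_degraded_psnr_lands_in_the_target_band(tiny_phantom_spec):
    """Default artifact magnitudes put the CBCT-domain fidelity in the
    mid-20s dB, the scale real degraded slices sit at."""
    vals = []
    for seed in range(4):
        img = generate_clean(tiny_phantom_spec, seed)
        vals.append(psnr(img, degrade(img, ArtifactSpec(), seed + 100)))
    assert 20 < float(np.mean(vals)) < 30
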