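"""Image-quality metrics: hand examples, closed forms and scalar oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage

from cbctcx.image_io import GrayImage
from cbctcx.metrics import (MetricReport, RoiMask, evaluate_pairs, format_report,
                            mae, mse, psnr, roi_mean_hu, ssim)
from cbctcx.phantom import ArtifactSpec, PhantomSpec, degrade, generate_clean, roi_masks


def gray(arr, **kw):
    return GrayImage(np.asarray(arr, dtype=np.uint16), **kw)


def ssim_oracle(x, y, data_range, win_size=11, sigma=1.5):
    """Gaussian-window SSIM written directly from the formula."""
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    truncate = ((win_size - 1) // 2) / sigma
    f = lambda a: ndimage.gaussian_filter(a, sigma, truncate=truncate)
    ux, uy = f(x), f(y)
    vx = f(x * x) - ux * ux
    vy = f(y * y) - uy * uy
    vxy = f(x * y) - ux * uy
    C1, C2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    s = ((2 * ux * uy + C1) * (2 * vxy + C2)) / ((ux ** 2 + uy ** 2 + C1) * (vx + vy + C2))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def test_mse_mae_hand_examples():
    a, b = gray([[0, 0]]), gray([[3, 4]])
    assert mse(a, b) == 12.5
    assert mae(a, b) == 3.5
    assert mse(a, a) == 0.0 and mae(a, a) == 0.0


def test_mse_mae_match_scalar_oracle(rng):
    x = rng.integers(0, 512, size=(9, 7))
    y = rng.integers(0, 512, size=(9, 7))
    se = ae = 0.0
    for i in range(9):
        for j in range(7):
            diff = float(x[i, j]) - float(y[i, j])
            se += diff * diff
            ae += abs(diff)
    assert mse(x, y) == pytest.approx(se / 63, abs=1e-10)
    assert mae(x, y) == pytest.approx(ae / 63, abs=1e-10)


def test_metrics_are_symmetric(rng):
    x = rng.integers(0, 512, size=(16, 16))
    y = rng.integers(0, 512, size=(16, 16))
    assert mse(x, y) == mse(y, x)
    assert mae(x, y) == mae(y, x)
    assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)


def test_psnr_closed_forms():
    # MSE = peak^2  ->  0 dB;  MSE = peak^2/10  ->  10 dB  (9-bit peak 511)
    x = gray(np.zeros((4, 4)))
    y = gray(np.full((4, 4), 511))
    assert psnr(x, y) == pytest.approx(0.0, abs=1e-9)
    # uniform error of 1 at 8 bits: 10*log10(255^2)
    a = np.zeros((4, 4), dtype=np.uint16)
    assert psnr(a, a + 1, n_bits=8) == pytest.approx(10 * math.log10(255 ** 2), abs=1e-9)
    assert psnr(x, x) == math.inf


def test_psnr_uses_511_not_512():
    x = np.zeros((2, 2), dtype=np.uint16)
    val = psnr(x, x + 1, n_bits=9)
    assert val == pytest.approx(10 * math.log10(511 ** 2), abs=1e-12)
    assert val != pytest.approx(10 * math.log10(512 ** 2), abs=1e-6)


def test_psnr_monotone_decreasing_in_mse(rng):
    x = gray(rng.integers(0, 512, size=(8, 8)))
    vals = [psnr(x, gray(np.clip(x.pixels.astype(int) + k, 0, 511))) for k in (1, 4, 16)]
    assert vals[0] > vals[1] > vals[2]


def test_mae_triangle_inequality(rng):
    x, y, z = (rng.integers(0, 512, size=(12, 12)) for _ in range(3))
    assert mae(x, z) <= mae(x, y) + mae(y, z) + 1e-12


def test_ssim_identity_and_anticorrelation(rng):
    x = rng.integers(0, 512, size=(32, 32)).astype(np.uint16)
    assert ssim(x, x) == pytest.approx(1.0)
    assert ssim(x, 511 - x) < 0


def test_ssim_matches_independent_formula(rng):
    x = rng.integers(0, 512, size=(48, 48))
    y = np.clip(x + rng.normal(0, 30, x.shape), 0, 511).astype(np.uint16)
    assert ssim(x, y, n_bits=9) == pytest.approx(ssim_oracle(x, y, 511), abs=1e-6)


def test_geometry_mismatch_raises():
    with pytest.raises(ValueError, match="geometry"):
        mse(np.zeros((2, 2)), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="geometry"):
        psnr(np.zeros((2, 2)), np.zeros((3, 2)))


def test_roi_mean_hu_examples():
    img = gray(np.full((4, 4), 250), hu_scale=4.0, hu_offset=-1000.0)
    mask = np.ones((4, 4), dtype=bool)
    assert roi_mean_hu(img, mask) == 0.0          # soft tissue at 0 HU
    half = np.zeros((4, 4), dtype=np.uint16)
    half[:2] = 100
    half[2:] = 300
    img2 = GrayImage(half, hu_scale=4.0, hu_offset=-1000.0)
    assert roi_mean_hu(img2, mask) == (4 * 100 - 1000 + 4 * 300 - 1000) / 2
    with pytest.raises(ValueError):
        roi_mean_hu(img, np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValueError):
        RoiMask(np.zeros((2, 2), dtype=bool), "empty")


def test_phantom_spine_roi_recovers_configured_bone_hu():
    spec = PhantomSpec(size=64, intensity_jitter=0.0, geom_jitter=0.0, nodules=())
    img = generate_clean(spec, 0)
    hu = roi_mean_hu(img, roi_masks(spec, 0)["bone"])
    assert hu == spec.bone_intensity * img.hu_scale + img.hu_offset


def test_evaluate_pairs_identity_model_reproduces_input_column():
    spec = PhantomSpec(size=64)
    pairs = []
    for seed in range(3):
        clean = generate_clean(spec, seed)
        pairs.append((degrade(clean, ArtifactSpec(), seed + 50), clean))
    report = evaluate_pairs(None, pairs)
    assert isinstance(report, MetricReport)
    assert report.n_images == 3
    assert report.corrected.psnr == pytest.approx(report.input.psnr, abs=1e-9)
    assert report.corrected.mae == pytest.approx(report.input.mae, abs=1e-9)


def test_evaluate_pairs_single_pair_equals_scalar_metrics():
    spec = PhantomSpec(size=64)
    clean = generate_clean(spec, 4)
    deg = degrade(clean, ArtifactSpec(), 9)
    report = evaluate_pairs(None, [(deg, clean)], rois=[roi_masks(spec, 4)])
    assert report.input.psnr == pytest.approx(psnr(clean, deg), abs=1e-12)
    assert report.input.ssim == pytest.approx(ssim(clean, deg), abs=1e-12)
    assert report.truth_roi_hu["bone"] == pytest.approx(
        roi_mean_hu(clean, roi_masks(spec, 4)["bone"]))
    text = format_report(report)
    assert "psnr" in text and "mean_hu[bone]" in text


def test_evaluate_pairs_rejects_empty_set():
    with pytest.raises(ValueError, match="empty"):
        evaluate_pairs(None, [])
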