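"""Image-quality metrics: MSE, PSNR, MAE, SSIM and ROI mean CT numbers.

PSNR uses the quantization peak ``2**n - 1`` (for the default 9-bit
data: 511, i.e. 512 gray levels):

    PSNR = 10 * log10((2**n - 1)**2 / MSE)   [dB]

SSIM follows the standard Gaussian-window formulation (11-pixel window,
sigma 1.5, stabilizers proportional to the squared dynamic range),
delegated to scikit-image.  ROI means are reported in Hounsfield units
through each image's affine HU map.  ``evaluate_pairs`` scores a paired
test set both for the raw degraded input and for the corrected output,
mirroring an input-column / corrected-column quantitative table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .image_io import GrayImage, from_unit_range, to_unit_range

__all__ = [
    "RoiMask",
    "MetricColumn",
    "MetricReport",
    "mse",
    "psnr",
    "mae",
    "ssim",
    "roi_mean_hu",
    "evaluate_pairs",
    "format_report",
]


@dataclass
class RoiMask:
    mask: np.ndarray
    label: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} selects no pixels")


def _pixels(x) -> np.ndarray:
    if isinstance(x, GrayImage):
        return x.pixels.astype(np.float64)
    return np.asarray(x, dtype=np.float64)


def _check_geometry(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")


def mse(x, g) -> float:
    """Mean squared pixel difference."""
    a, b = _pixels(x), _pixels(g)
    _check_geometry(a, b)
    return float(np.mean((a - b) ** 2))


def mae(x, g) -> float:
    """Mean absolute pixel difference (native intensity units)."""
    a, b = _pixels(x), _pixels(g)
    _check_geometry(a, b)
    return float(np.mean(np.abs(a - b)))


def psnr(x, g, n_bits: int | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    if n_bits is None:
        n_bits = x.n_bits if isinstance(x, GrayImage) else 9
    m = mse(x, g)
    if m == 0:
        return math.inf
    peak = (1 << n_bits) - 1
    return float(10.0 * np.log10(peak ** 2 / m))


def ssim(x, g, window: int = 11, n_bits: int | None = None) -> float:
    """Structural similarity with a Gaussian window; 1 iff identical."""
    if n_bits is None:
        n_bits = x.n_bits if isinstance(x, GrayImage) else 9
    a, b = _pixels(x), _pixels(g)
    _check_geometry(a, b)
    if window > min(a.shape):
        raise ValueError(f"window {window} exceeds image extent {min(a.shape)}")
    return float(structural_similarity(
        a, b, win_size=window, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=(1 << n_bits) - 1))


def roi_mean_hu(img: GrayImage, mask) -> float:
    """Mean CT number (HU) over the selected pixels."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise ValueError(f"ROI geometry {m.shape} does not match image {img.shape}")
    if not m.any():
        raise ValueError("ROI selects no pixels")
    return float(img.to_hu()[m].mean())


@dataclass
class MetricColumn:
    psnr: float
    ssim: float
    mae: float
    mse: float
    roi_hu: dict = field(default_factory=dict)


@dataclass
class MetricReport:
    input: MetricColumn
    corrected: MetricColumn
    truth_roi_hu: dict
    n_images: int


class _IdentityModel:
    def correct(self, img01):
        return np.asarray(img01, dtype=np.float64)


def evaluate_pairs(model, pairs, rois=None) -> MetricReport:
    """Average metrics of a paired (degraded, truth) test set.

    model : object with ``correct(img01) -> img01`` (None = identity)
    pairs : iterable of (cbct: GrayImage, ct_truth: GrayImage)
    rois  : optional list (one per pair) of {label: bool mask} dicts
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty test set")
    if rois is not None and len(rois) != len(pairs):
        raise ValueError("rois must align one-to-one with pairs")
    model = model if model is not None else _IdentityModel()

    cols = {"input": [], "corrected": []}
    hu = {"input": {}, "corrected": {}, "truth": {}}
    for k, (cbct, truth) in enumerate(pairs):
        corrected = from_unit_range(model.correct(to_unit_range(cbct)), cbct)
        for name, img in (("input", cbct), ("corrected", corrected)):
            cols[name].append((psnr(truth, img), ssim(truth, img),
                               mae(truth, img), mse(truth, img)))
            if rois is not None:
                for label, mask in rois[k].items():
                    hu[name].setdefault(label, []).append(roi_mean_hu(img, mask))
        if rois is not None:
            for label, mask in rois[k].items():
                hu["truth"].setdefault(label, []).append(roi_mean_hu(truth, mask))

    def column(name):
        arr = np.asarray(cols[name], dtype=np.float64)
        return MetricColumn(
            psnr=float(arr[:, 0].mean()), ssim=float(arr[:, 1].mean()),
            mae=float(arr[:, 2].mean()), mse=float(arr[:, 3].mean()),
            roi_hu={l: float(np.mean(v)) for l, v in hu[name].items()})

    return MetricReport(input=column("input"), corrected=column("corrected"),
                        truth_roi_hu={l: float(np.mean(v)) for l, v in hu["truth"].items()},
                        n_images=len(pairs))


def format_report(report: MetricReport) -> str:
    """Plain-text table: one metric per row, input / corrected columns."""
    lines = [f"n_images\t{report.n_images}",
             "metric\tinput\tcorrected\ttruth"]
    for label in sorted(report.truth_roi_hu):
        lines.append(f"mean_hu[{label}]\t{report.input.roi_hu[label]:.2f}\t"
                     f"{report.corrected.roi_hu[label]:.2f}\t"
                     f"{report.truth_roi_hu[label]:.2f}")
    for name in ("psnr", "ssim", "mae", "mse"):
        a = getattr(report.input, name)
        b = getattr(report.corrected, name)
        lines.append(f"{name}\t{a:.4f}\t{b:.4f}\t-")
    return "\n".join(lines) + "\n"
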