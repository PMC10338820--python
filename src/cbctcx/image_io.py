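"""Reading and writing 2-D grayscale tomographic slices.

The native on-disk dialect is headerless raw: unsigned 16-bit
little-endian samples, row-major, no header — the common CT export
convention.  Geometry and quantization are supplied by the caller or by
a JSON sidecar written next to the raw file.  Lossless 16-bit PNG/TIFF
are supported through imageio; lossy formats are rejected.

Intensities are quantized to ``n_bits`` (default 9, i.e. 512 gray
levels spanning [0, 511]).  An affine map per image converts stored
intensity to Hounsfield units: ``HU = intensity * hu_scale + hu_offset``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "quantize",
    "read_raw",
    "write_raw",
    "read_image",
    "write_image",
    "to_unit_range",
    "from_unit_range",
]

DEFAULT_N_BITS = 9
# defaults put air at -1000 HU, soft tissue (level 250) at 0 HU and the
# phantom's bone (level ~308) near +230 HU
DEFAULT_HU_SCALE = 4.0
DEFAULT_HU_OFFSET = -1000.0

_LOSSY_EXT = {".jpg", ".jpeg", ".webp"}


@dataclass
class GrayImage:
    """One 2-D single-channel slice with quantization and HU metadata.

    pixels : uint16 array, values in ``[0, 2**n_bits - 1]``
    n_bits : quantization depth
    hu_offset, hu_scale : affine map from stored intensity to HU
    """

    pixels: np.ndarray
    n_bits: int = DEFAULT_N_BITS
    hu_scale: float = DEFAULT_HU_SCALE
    hu_offset: float = DEFAULT_HU_OFFSET

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D grid, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint16:
            arr = np.asarray(self.pixels, dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError("pixel intensities must be finite")
            self.pixels = quantize(arr, self.n_bits)
        if self.hu_scale == 0:
            raise ValueError("hu_scale must be nonzero (the HU map must be invertible)")
        peak = (1 << self.n_bits) - 1
        if self.pixels.max() > peak:
            raise ValueError(f"intensity {self.pixels.max()} exceeds {peak} for n_bits={self.n_bits}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def peak(self) -> int:
        return (1 << self.n_bits) - 1

    def to_hu(self) -> np.ndarray:
        return self.pixels.astype(np.float64) * self.hu_scale + self.hu_offset

    def with_pixels(self, arr) -> "GrayImage":
        return GrayImage(arr, n_bits=self.n_bits, hu_scale=self.hu_scale, hu_offset=self.hu_offset)


def quantize(arr: np.ndarray, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Round-half-up to integer gray levels, clamped to [0, 2**n_bits - 1]."""
    peak = (1 << n_bits) - 1
    q = np.floor(np.asarray(arr, dtype=np.float64) + 0.5)
    return np.clip(q, 0, peak).astype(np.uint16)


def _sidecar_path(path: str) -> str:
    return str(path) + ".json"


def write_raw(img: GrayImage, path, sample_bytes: int = 2) -> None:
    """Write headerless raw plus a JSON geometry sidecar.

    The default dialect is unsigned 16-bit little-endian; single-byte
    samples are available for quantization depths of 8 bits or less.
    """
    if sample_bytes not in (1, 2):
        raise ValueError("sample_bytes must be 1 or 2")
    if sample_bytes == 1 and img.n_bits > 8:
        raise ValueError(f"{img.n_bits}-bit data does not fit single-byte samples")
    h, w = img.shape
    img.pixels.astype("u1" if sample_bytes == 1 else "<u2").tofile(str(path))
    meta = {
        "height": h,
        "width": w,
        "n_bits": img.n_bits,
        "hu_scale": img.hu_scale,
        "hu_offset": img.hu_offset,
        "sample_bytes": sample_bytes,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh)


def read_raw(path, height: int | None = None, width: int | None = None,
             n_bits: int | None = None, hu_scale: float | None = None,
             hu_offset: float | None = None, sample_bytes: int | None = None) -> GrayImage:
    """Read a headerless raw slice (uint16-LE by default).

    Geometry may be given explicitly or picked up from the JSON sidecar
    written by :func:`write_raw`; explicit arguments win.
    """
    meta = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    height = height if height is not None else meta.get("height")
    width = width if width is not None else meta.get("width")
    if height is None or width is None:
        raise ValueError(f"geometry for {path!s} not given and no sidecar found")
    n_bits = n_bits if n_bits is not None else meta.get("n_bits", DEFAULT_N_BITS)
    hu_scale = hu_scale if hu_scale is not None else meta.get("hu_scale", DEFAULT_HU_SCALE)
    hu_offset = hu_offset if hu_offset is not None else meta.get("hu_offset", DEFAULT_HU_OFFSET)
    sample_bytes = sample_bytes if sample_bytes is not None else meta.get("sample_bytes", 2)
    if sample_bytes not in (1, 2):
        raise ValueError("sample_bytes must be 1 or 2")

    expected = height * width * sample_bytes
    actual = os.path.getsize(str(path))
    if actual != expected:
        raise ValueError(
            f"raw size mismatch for {path!s}: expected {height}x{width}x{sample_bytes} = "
            f"{expected} bytes, found {actual}")
    dtype = "u1" if sample_bytes == 1 else "<u2"
    data = np.fromfile(str(path), dtype=dtype).reshape(height, width)
    peak = (1 << n_bits) - 1
    data = np.minimum(data, peak).astype(np.uint16)
    return GrayImage(data, n_bits=n_bits, hu_scale=hu_scale, hu_offset=hu_offset)


def write_image(img: GrayImage, path) -> None:
    """Write a lossless 16-bit PNG/TIFF; lossy formats are rejected."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _LOSSY_EXT:
        raise ValueError(f"lossy format {ext!r} refused; use raw, PNG or TIFF")
    iio.imwrite(str(path), img.pixels.astype(np.uint16))


def read_image(path, n_bits: int = DEFAULT_N_BITS,
               hu_scale: float = DEFAULT_HU_SCALE,
               hu_offset: float = DEFAULT_HU_OFFSET) -> GrayImage:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in _LOSSY_EXT:
        raise ValueError(f"lossy format {ext!r} refused; use raw, PNG or TIFF")
    data = np.asarray(iio.imread(str(path)))
    if data.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {data.shape}")
    peak = (1 << n_bits) - 1
    data = np.minimum(data.astype(np.int64), peak).astype(np.uint16)
    return GrayImage(data, n_bits=n_bits, hu_scale=hu_scale, hu_offset=hu_offset)


def to_unit_range(img: GrayImage) -> np.ndarray:
    """Map stored intensities linearly onto [0, 1] (divide by 2**n_bits - 1)."""
    return img.pixels.astype(np.float64) / img.peak


def from_unit_range(arr: np.ndarray, like: GrayImage) -> GrayImage:
    """Inverse of :func:`to_unit_range`, re-quantizing to ``like.n_bits``."""
    return like.with_pixels(np.asarray(arr, dtype=np.float64) * like.peak)
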