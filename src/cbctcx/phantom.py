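"""Synthetic thorax phantoms and CBCT-style artifact degradation.

The clean phantom is a piecewise-constant axial chest slice: an
elliptical body with a skin rim, two air-filled lungs, a posterior
vertebral body, a ring of ribs, and optional lung nodules with
spiculation rays and vacuole holes.  Tissue classes are ordered
air < lung < skin/soft tissue < bone; with zero jitter every class
renders at exactly its configured mean gray level, which makes ROI
statistics analytically checkable.

Degradation is phenomenological, not physics-based: a multiplicative
radial cup field (center-dark grayscale depression), a directional
low-frequency shading field, additive streak rays with Gaussian
cross-profile, and Gaussian noise.  A smooth elastic warp is available
separately to break spatial alignment between the two training domains.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import GrayImage, quantize, write_raw

__all__ = [
    "Nodule",
    "PhantomSpec",
    "ArtifactSpec",
    "generate_clean",
    "roi_masks",
    "degrade",
    "cup_field",
    "shadow_field",
    "elastic_warp",
    "PhantomDataset",
    "make_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class Nodule:
    """A lung lesion: disk of elevated intensity, optional spiculation
    rays (thin radial spokes) and vacuole sub-holes (small lucencies)."""

    center: tuple[float, float] = (-0.05, 0.38)   # (y, x) in [-1, 1] coords
    radius: float = 0.07
    contrast: float = 170.0                        # gray levels above lung
    spicule_rays: int = 0
    vacuoles: int = 0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic thorax slice."""

    size: int = 64
    n_bits: int = 9
    # all geometry in normalized [-1, 1] image coordinates (y down, x right)
    body_axes: tuple[float, float] = (0.72, 0.88)          # (a_y, a_x)
    skin_thickness: float = 0.07                           # fraction of body axes
    lung_axes: tuple[tuple[float, float], ...] = ((0.42, 0.30), (0.42, 0.30))
    lung_centers: tuple[tuple[float, float], ...] = ((-0.08, -0.42), (-0.08, 0.42))
    spine_radius: float = 0.14
    spine_center: tuple[float, float] = (0.48, 0.0)
    rib_count: int = 8
    rib_thickness: float = 0.045
    nodules: tuple[Nodule, ...] = (Nodule(spicule_rays=5, vacuoles=1),)
    # class mean gray levels (9-bit scale); air outside the body is 0
    lung_intensity: float = 55.0
    soft_intensity: float = 250.0
    skin_intensity: float = 215.0
    bone_intensity: float = 308.0
    intensity_jitter: float = 8.0                          # uniform +- gray levels
    geom_jitter: float = 0.03                              # uniform +- on centers/axes

    def __post_init__(self):
        if self.size < 16:
            raise ValueError("phantom size must be at least 16")
        if not (0 < self.lung_intensity < self.soft_intensity < self.bone_intensity):
            raise ValueError("tissue intensities must be ordered lung < soft < bone")
        margin = self.geom_jitter
        ay, ax = self.body_axes
        if ay + margin > 1 or ax + margin > 1:
            raise ValueError("body ellipse (plus jitter) must lie inside the image")
        for (cy, cx), (ly, lx) in zip(self.lung_centers, self.lung_axes):
            if abs(cy) + ly + margin > 1 or abs(cx) + lx + margin > 1:
                raise ValueError("lung ellipse (plus jitter) must lie inside the image")
        sy, sx = self.spine_center
        if abs(sy) + self.spine_radius + margin > 1 or abs(sx) + self.spine_radius + margin > 1:
            raise ValueError("spine disk (plus jitter) must lie inside the image")
        peak = (1 << self.n_bits) - 1
        if self.bone_intensity + self.intensity_jitter > peak:
            raise ValueError(f"bone intensity plus jitter exceeds peak {peak}")


@dataclass(frozen=True)
class ArtifactSpec:
    """CBCT-style degradation parameters.

    Amplitudes are fractional for the multiplicative fields and in gray
    levels for streaks and noise; `deform_amplitude` (pixels) drives the
    elastic warp used to de-align the clean training domain.
    """

    cup_amplitude: float = 0.18
    cup_exponent: float = 2.0
    shadow_amplitude: float = 0.10
    shadow_direction: float = 35.0                         # degrees
    streak_count: int = 12
    streak_amplitude: float = 35.0
    streak_sigma: float = 1.0                              # pixels, cross-profile
    noise_sigma: float = 6.0
    deform_amplitude: float = 1.5                          # pixels

    def __post_init__(self):
        for name in ("cup_amplitude", "shadow_amplitude", "streak_amplitude",
                     "noise_sigma", "deform_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def is_identity(self) -> bool:
        return (self.cup_amplitude == 0 and self.shadow_amplitude == 0
                and (self.streak_count == 0 or self.streak_amplitude == 0)
                and self.noise_sigma == 0)


def _grid(size: int):
    c = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    return np.meshgrid(c, c, indexing="ij")    # yy, xx


def _ellipse(yy, xx, center, axes):
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


@dataclass
class _Layout:
    """Jittered geometry and class intensities drawn for one phantom."""
    body_axes: tuple
    lung_centers: tuple
    lung_axes: tuple
    spine_center: tuple
    rib_angles: np.ndarray
    nodules: tuple
    levels: dict


def _draw_layout(spec: PhantomSpec, seed: int) -> _Layout:
    rng = np.random.default_rng(seed)
    gj, ij = spec.geom_jitter, spec.intensity_jitter
    jit = lambda: rng.uniform(-gj, gj)
    body_axes = (spec.body_axes[0] + jit(), spec.body_axes[1] + jit())
    lung_centers = tuple((cy + jit(), cx + jit()) for cy, cx in spec.lung_centers)
    lung_axes = tuple((ay + jit() * 0.5, ax + jit() * 0.5) for ay, ax in spec.lung_axes)
    spine_center = (spec.spine_center[0] + jit(), spec.spine_center[1] + jit())
    rib_angles = (np.linspace(0, 2 * np.pi, spec.rib_count, endpoint=False)
                  + rng.uniform(-0.1, 0.1, spec.rib_count)) if spec.rib_count else np.array([])
    nodules = tuple(
        replace(n, center=(n.center[0] + jit() * 0.5, n.center[1] + jit() * 0.5))
        for n in spec.nodules)
    levels = {
        "lung": spec.lung_intensity + rng.uniform(-ij, ij),
        "soft": spec.soft_intensity + rng.uniform(-ij, ij),
        "skin": spec.skin_intensity + rng.uniform(-ij, ij),
        "bone": spec.bone_intensity + rng.uniform(-ij, ij),
    }
    return _Layout(body_axes, lung_centers, lung_axes, spine_center,
                   rib_angles, nodules, levels)


def _render(spec: PhantomSpec, lay: _Layout) -> np.ndarray:
    yy, xx = _grid(spec.size)
    img = np.zeros((spec.size, spec.size))
    body = _ellipse(yy, xx, (0.0, 0.0), lay.body_axes)
    inner_axes = (lay.body_axes[0] * (1 - spec.skin_thickness),
                  lay.body_axes[1] * (1 - spec.skin_thickness))
    inner = _ellipse(yy, xx, (0.0, 0.0), inner_axes)
    img[body] = lay.levels["skin"]
    img[inner] = lay.levels["soft"]
    lung_masks = []
    for center, axes in zip(lay.lung_centers, lay.lung_axes):
        m = _ellipse(yy, xx, center, axes)
        lung_masks.append(m)
        img[m] = lay.levels["lung"]
    # ribs sit on a ring just inside the body outline
    ring = (lay.body_axes[0] * 0.88, lay.body_axes[1] * 0.88)
    for ang in lay.rib_angles:
        c = (ring[0] * np.sin(ang), ring[1] * np.cos(ang))
        img[_ellipse(yy, xx, c, (spec.rib_thickness, spec.rib_thickness))] = lay.levels["bone"]
    spine = _ellipse(yy, xx, lay.spine_center, (spec.spine_radius, spec.spine_radius))
    img[spine] = lay.levels["bone"]
    for nod in lay.nodules:
        level = lay.levels["lung"] + nod.contrast
        m = _ellipse(yy, xx, nod.center, (nod.radius, nod.radius))
        img[m] = level
        if nod.spicule_rays:
            angles = np.linspace(0, 2 * np.pi, nod.spicule_rays, endpoint=False)
            for k, ang in enumerate(angles):
                for t in np.linspace(nod.radius, nod.radius * 2.2, 12):
                    c = (nod.center[0] + t * np.sin(ang), nod.center[1] + t * np.cos(ang))
                    ray = _ellipse(yy, xx, c, (0.012, 0.012))
                    img[ray] = level
        for v in range(nod.vacuoles):
            ang = 2 * np.pi * (v + 0.3) / max(nod.vacuoles, 1)
            c = (nod.center[0] + 0.4 * nod.radius * np.sin(ang),
                 nod.center[1] + 0.4 * nod.radius * np.cos(ang))
            img[_ellipse(yy, xx, c, (nod.radius * 0.22, nod.radius * 0.22))] = lay.levels["lung"]
    return img


def generate_clean(spec: PhantomSpec, seed: int) -> GrayImage:
    """Render one clean CT-like slice; deterministic in (spec, seed)."""
    lay = _draw_layout(spec, seed)
    return GrayImage(quantize(_render(spec, lay), spec.n_bits), n_bits=spec.n_bits)


def roi_masks(spec: PhantomSpec, seed: int) -> dict[str, np.ndarray]:
    """Boolean ROI masks matching the slice `generate_clean(spec, seed)`.

    `bone` is the vertebral disk, `skin` the body rim, `lung` the union
    of both lung fields (nodules excluded from none of them — masks are
    geometric, matching how a fixed ROI would be placed on real data).
    """
    lay = _draw_layout(spec, seed)
    yy, xx = _grid(spec.size)
    body = _ellipse(yy, xx, (0.0, 0.0), lay.body_axes)
    inner_axes = (lay.body_axes[0] * (1 - spec.skin_thickness),
                  lay.body_axes[1] * (1 - spec.skin_thickness))
    inner = _ellipse(yy, xx, (0.0, 0.0), inner_axes)
    lungs = np.zeros_like(body)
    for center, axes in zip(lay.lung_centers, lay.lung_axes):
        lungs |= _ellipse(yy, xx, center, axes)
    spine = _ellipse(yy, xx, lay.spine_center, (spec.spine_radius, spec.spine_radius))
    return {"bone": spine, "skin": body & ~inner, "lung": lungs}


def cup_field(size: int, amplitude: float, exponent: float) -> np.ndarray:
    """Multiplicative cup bias ``1 - a * (1 - r**p)``: darkest at center,
    unity at the image rim (r normalized to 1 at the inscribed circle)."""
    yy, xx = _grid(size)
    r = np.minimum(np.sqrt(yy ** 2 + xx ** 2), 1.0)
    return 1.0 - amplitude * (1.0 - r ** exponent)


def shadow_field(size: int, amplitude: float, direction_deg: float) -> np.ndarray:
    """Directional linear shading field ``1 + a * u/2`` with u the signed
    position along `direction_deg`, in [-1, 1]."""
    yy, xx = _grid(size)
    th = np.deg2rad(direction_deg)
    u = xx * np.cos(th) + yy * np.sin(th)
    return 1.0 + amplitude * u / 2.0


def degrade(img: GrayImage, art: ArtifactSpec, seed: int) -> GrayImage:
    """Apply cup + shadow + streaks + noise; deterministic in seed.

    With all amplitudes zero the output equals the input exactly.
    """
    rng = np.random.default_rng(seed)
    size_y, size_x = img.shape
    if size_y != size_x:
        raise ValueError("degrade expects square slices")
    x = img.pixels.astype(np.float64)
    if art.is_identity():
        return img.with_pixels(img.pixels.copy())
    y = x * cup_field(size_y, art.cup_amplitude, art.cup_exponent)
    y *= shadow_field(size_y, art.shadow_amplitude, art.shadow_direction)
    if art.streak_count and art.streak_amplitude:
        yy, xx = _grid(size_y)
        sigma_n = art.streak_sigma * 2.0 / size_y
        for _ in range(art.streak_count):
            ang = rng.uniform(0, np.pi)
            cy, cx = rng.uniform(-0.5, 0.5, 2)
            amp = art.streak_amplitude * rng.choice((-1.0, 1.0))
            d = np.abs((xx - cx) * np.sin(ang) - (yy - cy) * np.cos(ang))
            y += amp * np.exp(-d ** 2 / (2 * sigma_n ** 2))
    if art.noise_sigma:
        y += rng.normal(0.0, art.noise_sigma, y.shape)
    return img.with_pixels(quantize(y, img.n_bits))


def elastic_warp(img: GrayImage, amplitude_px: float, seed: int,
                 smooth_sigma: float = 6.0) -> GrayImage:
    """Smooth random displacement field (Gaussian-filtered noise scaled to
    `amplitude_px` RMS), bilinear resampling with reflected borders."""
    if amplitude_px == 0:
        return img.with_pixels(img.pixels.copy())
    rng = np.random.default_rng(seed)
    h, w = img.shape
    disp = rng.standard_normal((2, h, w))
    disp = ndimage.gaussian_filter(disp, sigma=(0, smooth_sigma, smooth_sigma))
    rms = np.sqrt((disp ** 2).mean())
    disp = disp / max(rms, 1e-12) * amplitude_px
    iy, ix = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([iy + disp[0], ix + disp[1]])
    out = ndimage.map_coordinates(img.pixels.astype(np.float64), coords,
                                  order=1, mode="reflect")
    return img.with_pixels(quantize(out, img.n_bits))


@dataclass
class PhantomDataset:
    """Unpaired training split plus paired held-out test split."""

    train_cbct: list
    train_ct: list
    test_cbct: list
    test_ct: list
    manifest: list            # dict rows: filename, domain, split, anatomy_seed, artifact_seed
    spec: PhantomSpec
    test_anatomy_seeds: list


def make_dataset(n_train: int, n_test: int, spec: PhantomSpec, art: ArtifactSpec,
                 seed: int, out_dir=None) -> PhantomDataset:
    """Build an unpaired train split and a paired test split.

    The CBCT-domain and CT-domain training images come from disjoint
    anatomy seeds, and the CT-domain slices additionally get a smooth
    elastic warp, so no aligned pair exists in training.  Test pairs
    share their anatomy seed: clean truth plus its degraded counterpart.
    """
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    rng = np.random.default_rng(seed)
    base = int(rng.integers(0, 2 ** 30))
    art_base = int(rng.integers(0, 2 ** 30))
    warp_base = int(rng.integers(0, 2 ** 30))

    train_cbct, train_ct, test_cbct, test_ct, manifest = [], [], [], [], []
    for i in range(n_train):
        a_seed = base + i
        img = degrade(generate_clean(spec, a_seed), art, art_base + i)
        train_cbct.append(img)
        manifest.append({"filename": f"train_cbct_{i:04d}.raw", "domain": "cbct",
                         "split": "train", "anatomy_seed": a_seed,
                         "artifact_seed": art_base + i})
    for i in range(n_train):
        a_seed = base + n_train + i
        img = elastic_warp(generate_clean(spec, a_seed), art.deform_amplitude,
                           warp_base + i)
        train_ct.append(img)
        manifest.append({"filename": f"train_ct_{i:04d}.raw", "domain": "ct",
                         "split": "train", "anatomy_seed": a_seed,
                         "artifact_seed": -1})
    test_seeds = []
    for i in range(n_test):
        a_seed = base + 2 * n_train + i
        test_seeds.append(a_seed)
        clean = generate_clean(spec, a_seed)
        test_ct.append(clean)
        manifest.append({"filename": f"test_ct_{i:04d}.raw", "domain": "ct",
                         "split": "test", "anatomy_seed": a_seed, "artifact_seed": -1})
        degraded = degrade(clean, art, art_base + n_train + i)
        test_cbct.append(degraded)
        manifest.append({"filename": f"test_cbct_{i:04d}.raw", "domain": "cbct",
                         "split": "test", "anatomy_seed": a_seed,
                         "artifact_seed": art_base + n_train + i})
    ds = PhantomDataset(train_cbct, train_ct, test_cbct, test_ct, manifest, spec, test_seeds)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


_SPLIT_LISTS = {("train", "cbct"): "train_cbct", ("train", "ct"): "train_ct",
                ("test", "cbct"): "test_cbct", ("test", "ct"): "test_ct"}


def write_dataset(ds: PhantomDataset, out_dir) -> None:
    os.makedirs(str(out_dir), exist_ok=True)
    by_name = {}
    for key, attr in _SPLIT_LISTS.items():
        rows = [r for r in ds.manifest if (r["split"], r["domain"]) == key]
        for row, img in zip(rows, getattr(ds, attr)):
            by_name[row["filename"]] = img
    for row in ds.manifest:
        write_raw(by_name[row["filename"]], os.path.join(str(out_dir), row["filename"]))
    cols = ["filename", "domain", "split", "anatomy_seed", "artifact_seed"]
    with open(os.path.join(str(out_dir), "manifest.tsv"), "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in ds.manifest:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def load_dataset(in_dir) -> PhantomDataset:
    from .image_io import read_raw
    rows = []
    with open(os.path.join(str(in_dir), "manifest.tsv")) as fh:
        cols = fh.readline().strip().split("\t")
        for line in fh:
            vals = line.strip().split("\t")
            row = dict(zip(cols, vals))
            row["anatomy_seed"] = int(row["anatomy_seed"])
            row["artifact_seed"] = int(row["artifact_seed"])
            rows.append(row)
    lists = {attr: [] for attr in _SPLIT_LISTS.values()}
    for row in rows:
        attr = _SPLIT_LISTS[(row["split"], row["domain"])]
        lists[attr].append(read_raw(os.path.join(str(in_dir), row["filename"])))
    test_seeds = [r["anatomy_seed"] for r in rows
                  if r["split"] == "test" and r["domain"] == "ct"]
    return PhantomDataset(manifest=rows, spec=PhantomSpec(), test_anatomy_seeds=test_seeds,
                          **lists)


def dataset_hash(ds: PhantomDataset) -> str:
    """SHA-256 over every image's bytes plus the manifest (stability check)."""
    h = hashlib.sha256()
    for attr in ("train_cbct", "train_ct", "test_cbct", "test_ct"):
        for img in getattr(ds, attr):
            h.update(img.pixels.tobytes())
    for row in ds.manifest:
        h.update(repr(sorted(row.items())).encode())
    return h.hexdigest()
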