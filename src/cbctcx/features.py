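"""Deep feature-set extraction for the contextual loss.

The extractor mirrors the convolutional part of VGG19 — sixteen 3x3
convolutions in five blocks (64/128/256/512/512 channels) with ReLU
after every convolution and 2x2 max pooling between blocks.  The fully
connected head is never built.  Grayscale slices are replicated to
three identical channels before extraction, so a pretrained RGB
network sees them unchanged.

Two weight modes exist:

* pretrained weights loaded from a local ``.npz`` file (arrays named
  ``conv1_1.weight`` / ``conv1_1.bias`` ... in (C_out, C_in, k, k) layout);
* a seeded fixed random-weight network of the same topology (He
  initialization), which is what the test-suite and the bundled
  experiments use.  The contextual-loss mathematics is agnostic to the
  weight values; only feature determinism matters.

A ``width_scale`` knob shrinks all channel widths proportionally for
desk-scale runs without changing the topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d

__all__ = [
    "VGG19_LAYERS",
    "FeatureSet",
    "FeatureExtractor",
    "expand_channels",
    "sample_features",
    "equalize_sizes",
]

# (layer name, output channels); "pool" marks 2x2 max pooling
VGG19_LAYERS = (
    ("conv1_1", 64), ("conv1_2", 64), "pool",
    ("conv2_1", 128), ("conv2_2", 128), "pool",
    ("conv3_1", 256), ("conv3_2", 256), ("conv3_3", 256), ("conv3_4", 256), "pool",
    ("conv4_1", 512), ("conv4_2", 512), ("conv4_3", 512), ("conv4_4", 512), "pool",
    ("conv5_1", 512), ("conv5_2", 512), ("conv5_3", 512), ("conv5_4", 512),
)

# fixed input standardization applied after channel replication
INPUT_MEAN = 0.449
INPUT_STD = 0.226


@dataclass
class FeatureSet:
    """The N feature vectors harvested from one extractor layer.

    vectors : (N, D) array, one row per spatial location
    source_shape : (h, w) response-map geometry the rows were flattened from
    """

    layer_id: str
    vectors: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1 or self.vectors.shape[1] < 1:
            raise ValueError(f"vectors must be (N>=1, D>=1), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def expand_channels(img: np.ndarray) -> np.ndarray:
    """Replicate one grayscale channel into three identical channels."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {img.shape}")
    return np.repeat(img[None], 3, axis=0)


def _layer_table():
    table, depth = {}, 0
    for entry in VGG19_LAYERS:
        if entry == "pool":
            depth += 1
        else:
            name, ch = entry
            table[name] = (len(table), ch, depth)   # (conv index, channels, #pools before)
    return table


_LAYER_TABLE = _layer_table()


class FeatureExtractor:
    """Frozen convolutional feature extractor (VGG19 topology)."""

    def __init__(self, weights: dict | None = None, seed: int = 0,
                 width_scale: float = 1.0,
                 input_mean: float = INPUT_MEAN, input_std: float = INPUT_STD):
        if width_scale <= 0 or width_scale > 1:
            raise ValueError("width_scale must be in (0, 1]")
        self.seed = seed
        self.width_scale = width_scale
        self.input_mean = input_mean
        self.input_std = input_std
        self._params: dict[str, tuple[Tensor, Tensor]] = {}
        self._pretrained = weights is not None
        if weights is not None:
            for name in _LAYER_TABLE:
                wkey, bkey = f"{name}.weight", f"{name}.bias"
                if wkey in weights:
                    self._params[name] = (Tensor(weights[wkey]), Tensor(weights[bkey]))

    @classmethod
    def from_npz(cls, path, **kw) -> "FeatureExtractor":
        with np.load(str(path)) as npz:
            return cls(weights={k: npz[k] for k in npz.files}, **kw)

    def _width(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_scale)))

    def _param(self, name: str) -> tuple[Tensor, Tensor]:
        """He-initialized weights, lazily built, deterministic per layer."""
        if name not in self._params:
            if self._pretrained:
                raise KeyError(f"pretrained weight file has no arrays for layer {name!r}")
            idx, ch, _ = _LAYER_TABLE[name]
            c_out = self._width(ch)
            c_in = 3 if idx == 0 else self._width(self._prev_channels(name))
            rng = np.random.default_rng((self.seed, idx))
            w = rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / (c_in * 9))
            self._params[name] = (Tensor(w), Tensor(np.zeros(c_out)))
        return self._params[name]

    @staticmethod
    def _prev_channels(name: str) -> int:
        idx = _LAYER_TABLE[name][0]
        for prev, (i, ch, _) in _LAYER_TABLE.items():
            if i == idx - 1:
                return ch
        raise KeyError(name)

    # -- forward paths -------------------------------------------------------
    def _check_geometry(self, h: int, w: int, layers) -> None:
        max_pools = max(_LAYER_TABLE[l][2] for l in layers)
        f = 2 ** max_pools
        if h % f or w % f or h // f < 1 or w // f < 1:
            raise ValueError(
                f"input {h}x{w} cannot survive {max_pools} pooling stages "
                f"required by layers {sorted(layers)} (needs divisibility by {f})")

    def forward_tensor(self, x: Tensor, layers) -> dict[str, Tensor]:
        """Differentiable path: `x` is (H, W) or (1|3, H, W); returns
        (N, D) feature tensors per requested layer (post-ReLU responses)."""
        layers = list(layers)
        unknown = [l for l in layers if l not in _LAYER_TABLE]
        if unknown:
            raise KeyError(f"unknown layer labels {unknown}")
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[0] == 1:
            from .autodiff import concat
            x = concat([x, x, x], axis=0)
        elif x.shape[0] != 3:
            raise ValueError(f"expected 1 or 3 channels, got {x.shape[0]}")
        self._check_geometry(x.shape[1], x.shape[2], layers)
        x = (x - self.input_mean) * (1.0 / self.input_std)

        wanted = set(layers)
        last_idx = max(_LAYER_TABLE[l][0] for l in layers)
        out: dict[str, Tensor] = {}
        h = x
        conv_idx = 0
        for entry in VGG19_LAYERS:
            if entry == "pool":
                h = maxpool2d(h, 2)
                continue
            name, _ = entry
            w, b = self._param(name)
            h = conv2d(h, w, b).relu()
            if name in wanted:
                c, hh, ww = h.shape
                out[name] = h.reshape(c, hh * ww).T   # (N, D)
            conv_idx += 1
            if conv_idx > last_idx:
                break
        return out

    def extract(self, img: np.ndarray, layers) -> dict[str, FeatureSet]:
        """Pure-numpy path: grayscale [0,1] image (2-D, or pre-expanded
        3-channel) to one FeatureSet per requested layer."""
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim == 2:
            arr = expand_channels(arr)
        elif arr.ndim == 3 and arr.shape[0] == 3:
            pass
        else:
            raise ValueError(f"expected (H,W) or (3,H,W), got {arr.shape}")
        feats = self.forward_tensor(Tensor(arr), list(layers))
        out = {}
        for name, t in feats.items():
            _, ch, depth = _LAYER_TABLE[name]
            f = 2 ** depth
            shape = (arr.shape[1] // f, arr.shape[2] // f)
            out[name] = FeatureSet(layer_id=name, vectors=t.data, source_shape=shape)
        return out


def sample_features(fs: FeatureSet, n_target: int, seed: int) -> FeatureSet:
    """Uniform subsample without replacement; deterministic given seed."""
    if n_target > fs.n:
        raise ValueError(f"cannot sample {n_target} from a set of {fs.n}")
    idx = sample_indices(fs.n, n_target, seed)
    return FeatureSet(layer_id=fs.layer_id, vectors=fs.vectors[idx],
                      source_shape=fs.source_shape)


def sample_indices(n: int, n_target: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=n_target, replace=False)


def equalize_sizes(s: FeatureSet, t: FeatureSet, seed: int,
                   cap: int | None = None) -> tuple[FeatureSet, FeatureSet]:
    """Sample the larger set down so |S| = |T| (optionally capped).

    Sets of equal original size share one index draw, so comparing a set
    with itself stays an identity comparison after sampling."""
    n = min(s.n, t.n) if cap is None else min(s.n, t.n, cap)
    same = s.n == t.n
    if s.n > n:
        s = sample_features(s, n, seed)
    if t.n > n:
        t = sample_features(t, n, seed if same else seed + 1)
    return s, t
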