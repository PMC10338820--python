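"""Feature-fusion residual network (FFRN) generator.

The generator stacks residual skip dense blocks (RSDB).  A front
adaptive convolution turns the one-channel slice into F_0,LF.  Block f
applies `convs_per_block` 3x3 convolutions with ReLU after each,
producing F_f,2; the local feature fusion (LFF) layer then concatenates
[F_0,LF, F_1,2, ..., F_f,2] along channels and fuses them back to the
base width with a 1x1 convolution.  The fused map skips past the block
and feeds the next one.  A final reconstruction convolution maps back
to one channel and a global residual adds the input slice, so the
all-zero-parameter network is exactly the identity map.

The fusion input of block f therefore carries (f+1) * base_channels
channels — the growing dense concatenation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d

__all__ = [
    "NetworkConfig",
    "FfrnModel",
    "build_ffrn",
    "correct_image",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    n_rsdb: int = 4
    base_channels: int = 32
    convs_per_block: int = 2     # convolutions producing F_f,2; fusion conv is extra
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_rsdb < 1:
            raise ValueError("n_rsdb must be at least 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be at least 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be at least 1")

    @classmethod
    def tiny(cls, seed: int = 0) -> "NetworkConfig":
        """Desk-scale profile: 2 blocks of 8 channels."""
        return cls(n_rsdb=2, base_channels=8, seed=seed)


class FfrnModel:
    """Generator G with seeded He initialization.

    Parameters live in an ordered name -> Tensor dict; the
    reconstruction convolution initializes to zero so a freshly built
    model starts at the identity map (global residual)."""

    def __init__(self, cfg: NetworkConfig, zero_init: bool = False):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(cfg.seed)
        C, k = cfg.base_channels, cfg.kernel_size

        def he(shape):
            fan_in = int(np.prod(shape[1:]))
            w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
            return np.zeros(shape) if zero_init else w

        self._add("front.weight", he((C, 1, k, k)))
        self._add("front.bias", np.zeros(C))
        for f in range(1, cfg.n_rsdb + 1):
            for c in range(1, cfg.convs_per_block + 1):
                self._add(f"rsdb{f}.conv{c}.weight", he((C, C, k, k)))
                self._add(f"rsdb{f}.conv{c}.bias", np.zeros(C))
            self._add(f"rsdb{f}.fuse.weight", he((C, (f + 1) * C, 1, 1)))
            self._add(f"rsdb{f}.fuse.bias", np.zeros(C))
        self._add("recon.weight", np.zeros((1, C, k, k)))
        self._add("recon.bias", np.zeros(1))

    def _add(self, name: str, arr: np.ndarray) -> None:
        self.params[name] = Tensor(arr, requires_grad=True)

    # -- structure queries ----------------------------------------------------
    def fusion_in_channels(self, f: int) -> int:
        """Channel count entering block f's fusion convolution."""
        return self.params[f"rsdb{f}.fuse.weight"].shape[1]

    def parameter_checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(self.params[name].data.tobytes())
        return h.hexdigest()

    def zero_(self) -> "FfrnModel":
        for t in self.params.values():
            t.data[...] = 0.0
        return self

    # -- forward --------------------------------------------------------------
    def rsdb_forward(self, f: int, f_prev: Tensor, stack: list[Tensor]) -> tuple[Tensor, Tensor]:
        """One block: returns (F_f,2, F_f,LF); `stack` holds
        [F_0,LF, F_1,2, ..., F_{f-1},2] and is appended in place."""
        C = self.cfg.base_channels
        if f_prev.shape[0] != C:
            raise ValueError(f"block {f} expects {C} input channels, got {f_prev.shape[0]}")
        h = f_prev
        for c in range(1, self.cfg.convs_per_block + 1):
            h = conv2d(h, self.params[f"rsdb{f}.conv{c}.weight"],
                       self.params[f"rsdb{f}.conv{c}.bias"]).relu()
        f_f2 = h
        stack.append(f_f2)
        fused = conv2d(concat(stack, axis=0),
                       self.params[f"rsdb{f}.fuse.weight"],
                       self.params[f"rsdb{f}.fuse.bias"])
        return f_f2, fused

    def forward_tensor(self, x: Tensor) -> Tensor:
        """x: (1, H, W) normalized slice -> (1, H, W) corrected slice."""
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[0] != 1:
            raise ValueError(f"expected a single-channel input, got {x.shape[0]} channels")
        f0 = conv2d(x, self.params["front.weight"], self.params["front.bias"]).relu()
        stack = [f0]
        f_prev = f0
        for f in range(1, self.cfg.n_rsdb + 1):
            _, f_prev = self.rsdb_forward(f, f_prev, stack)
        out = conv2d(f_prev, self.params["recon.weight"], self.params["recon.bias"])
        return out + x

    def correct(self, img01: np.ndarray) -> np.ndarray:
        """Inference on a [0,1] slice; output clamped back into [0,1]."""
        arr = np.asarray(img01, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D slice, got shape {arr.shape}")
        y = self.forward_tensor(Tensor(arr)).data[0]
        return np.clip(y, 0.0, 1.0)


def build_ffrn(cfg: NetworkConfig) -> FfrnModel:
    """Deterministic construction: same seed, same parameters."""
    return FfrnModel(cfg)


def correct_image(model: FfrnModel, img01: np.ndarray) -> np.ndarray:
    return model.correct(img01)


def save_checkpoint(model: FfrnModel, path) -> None:
    cfg = model.cfg
    meta = json.dumps({"n_rsdb": cfg.n_rsdb, "base_channels": cfg.base_channels,
                       "convs_per_block": cfg.convs_per_block,
                       "kernel_size": cfg.kernel_size, "seed": cfg.seed})
    np.savez(str(path), __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{k: v.data for k, v in model.params.items()})


def load_checkpoint(path) -> FfrnModel:
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["__config__"]).decode())
        model = FfrnModel(NetworkConfig(**meta))
        for name in model.params:
            model.params[name].data[...] = npz[name]
    return model
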