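"""Unpaired training of the FFRN generator under the contextual objective.

Each epoch pairs every CBCT-domain slice once, in shuffled order, with a
CT-domain slice drawn uniformly at random — the unpaired regime, where
the two domains never share anatomy.  Each step runs the generator,
extracts deep features of the output, and takes one Adam step on

    L(G) = lambda * L_CX(G(s), t, style layers) + L_CX(G(s), s, content layers).

The feature extractor is frozen; gradients flow only through the
generator.  Target (t) and content (s) features are constant across
epochs and are cached up front.  All randomness — pairing, feature
sampling, initialization — derives from one master seed, so a run is
fully reproducible on a fixed platform.

Defaults follow the reference protocol (Adam, learning rate 1e-4,
100 epochs, 3x3 kernels); the tiny desk-scale profile shortens this to
a few hundred steps at learning rate 1e-3.
"""

from __future__ import annotations

import math
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .autodiff import Tensor
from .cx import LossConfig, combined_loss_tensor
from .features import FeatureExtractor, sample_indices
from .ffrn import FfrnModel, NetworkConfig, save_checkpoint
from .image_io import to_unit_range, from_unit_range, write_raw
from .metrics import evaluate_pairs, format_report
from .phantom import ArtifactSpec, PhantomSpec, make_dataset, roi_masks, write_dataset

__all__ = [
    "TrainConfig",
    "TrainLog",
    "Adam",
    "pair_batches",
    "train",
    "run_experiment",
    "tiny_experiment_config",
]


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 1
    scheduler_step: int | None = None      # LR-decay interval in epochs (None = constant)
    scheduler_gamma: float = 0.5
    seed: int = 0
    dry_run: bool = False
    checkpoint_every: int = 0              # 0 = final checkpoint only
    loss_cfg: LossConfig = field(default_factory=LossConfig)
    net_cfg: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


@dataclass
class TrainLog:
    records: list = field(default_factory=list)   # per-epoch dicts

    def append(self, **rec):
        for v in rec.values():
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"non-finite log value in {rec}")
        self.records.append(rec)

    def losses(self):
        return [r["loss"] for r in self.records]

    def to_text(self) -> str:
        if not self.records:
            return ""
        cols = list(self.records[0])
        lines = ["\t".join(cols)]
        for r in self.records:
            lines.append("\t".join(
                f"{r[c]:.6f}" if isinstance(r[c], float) else str(r[c]) for c in cols))
        return "\n".join(lines) + "\n"

    def write(self, path):
        with open(str(path), "w") as fh:
            fh.write(self.to_text())


def pair_batches(cbct_set, ct_set, seed: int, epochs: int = 1):
    """Yield one list of (s_index, t_index) pairs per epoch.

    Every CBCT image appears exactly once per epoch (shuffled order);
    its CT partner is drawn uniformly at random.  Deterministic in seed.
    """
    n_s, n_t = len(cbct_set), len(ct_set)
    if n_s == 0 or n_t == 0:
        raise ValueError("both training domains must be non-empty")
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(n_s)
        partners = rng.integers(0, n_t, size=n_s)
        yield [(int(i), int(j)) for i, j in zip(order, partners)]


class Adam:
    """Adaptive-moment optimizer over a name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _all_layers(cfg: LossConfig):
    return sorted(set(cfg.style_layers) | set(cfg.content_layers))


def _cache_features(images, extractor, layers, cfg: LossConfig, seed: int):
    """Fixed per-image feature arrays, pre-sampled to the configured cap."""
    cached = []
    for k, img in enumerate(images):
        feats = extractor.extract(to_unit_range(img), layers)
        out = {}
        for l, fs in feats.items():
            vec = fs.vectors
            if vec.shape[0] > cfg.sample_n:
                vec = vec[sample_indices(vec.shape[0], cfg.sample_n, seed + 31 * k)]
            out[l] = vec
        cached.append(out)
    return cached


def train(model: FfrnModel, data, cfg: TrainConfig,
          extractor: FeatureExtractor | None = None) -> tuple[FfrnModel, TrainLog]:
    """Optimize the generator on an unpaired dataset.

    `data` needs `train_cbct` and `train_ct` lists of GrayImage.
    Returns the trained model and a per-epoch log.
    """
    log = TrainLog()
    if cfg.dry_run:
        return model, log
    extractor = extractor or FeatureExtractor(seed=cfg.loss_cfg.seed)
    layers = _all_layers(cfg.loss_cfg)
    rng = np.random.default_rng(cfg.seed)
    feat_seed = int(rng.integers(0, 2 ** 31))
    pair_seed = int(rng.integers(0, 2 ** 31))
    s_arrays = [to_unit_range(img) for img in data.train_cbct]
    s_feats = _cache_features(data.train_cbct, extractor, layers, cfg.loss_cfg, feat_seed)
    t_feats = _cache_features(data.train_ct, extractor, layers, cfg.loss_cfg, feat_seed + 7919)

    opt = Adam(model.params, lr=cfg.learning_rate)
    step = 0
    for epoch, pairs in enumerate(
            pair_batches(data.train_cbct, data.train_ct, pair_seed, cfg.epochs)):
        if cfg.scheduler_step and epoch > 0 and epoch % cfg.scheduler_step == 0:
            opt.lr *= cfg.scheduler_gamma
        t0 = time.perf_counter()
        ep_loss, ep_style, ep_content = [], [], []
        opt.zero_grad()
        in_batch = 0
        for s_idx, t_idx in pairs:
            g_out = model.forward_tensor(Tensor(s_arrays[s_idx]))
            g_feats = extractor.forward_tensor(g_out, layers)
            loss, style, content = combined_loss_tensor(
                g_feats, s_feats[s_idx], t_feats[t_idx], cfg.loss_cfg,
                seed=feat_seed + 101 * step)
            if not math.isfinite(float(loss.data)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, pair (s={s_idx}, t={t_idx})")
            loss.backward()
            ep_loss.append(float(loss.data))
            ep_style.append(style)
            ep_content.append(content)
            in_batch += 1
            step += 1
            if in_batch == cfg.batch_size:
                opt.step()
                opt.zero_grad()
                in_batch = 0
        if in_batch:
            opt.step()
            opt.zero_grad()
        log.append(epoch=epoch, loss=float(np.mean(ep_loss)),
                   style=float(np.mean(ep_style)), content=float(np.mean(ep_content)),
                   lr=opt.lr, seconds=time.perf_counter() - t0)
    return model, log


# -- experiment orchestration ------------------------------------------------

def tiny_experiment_config(seed: int = 0) -> dict:
    """Desk-scale end-to-end configuration: 64x64 phantoms, 2 RSDBs of 8
    channels, quarter-width random extractor, a few hundred Adam steps."""
    return {
        "seed": seed,
        "phantom": {"size": 64},
        "artifact": {},
        "network": {"n_rsdb": 2, "base_channels": 8},
        # at 64x64 the shallow layers' receptive fields match the scale of
        # the grayscale nonuniformity; the deeper library defaults suit
        # full-resolution slices
        "loss": {"sample_n": 512, "style_layers": ["conv1_2", "conv2_2"],
                 "content_layers": ["conv2_2"]},
        "extractor": {"width_scale": 0.25},
        "train": {"epochs": 25, "learning_rate": 1e-3, "batch_size": 1},
        "dataset": {"n_train": 8, "n_test": 4},
    }


def _build_from_config(config: dict):
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    sub = {name: int(rng.integers(0, 2 ** 31))
           for name in ("data", "net", "loss", "train", "extractor")}
    spec = PhantomSpec(**config.get("phantom", {}))
    art = ArtifactSpec(**config.get("artifact", {}))
    net_cfg = NetworkConfig(seed=sub["net"], **config.get("network", {}))
    loss_cfg = LossConfig(seed=sub["loss"], **config.get("loss", {}))
    extractor = FeatureExtractor(seed=sub["extractor"], **config.get("extractor", {}))
    train_cfg = TrainConfig(seed=sub["train"], loss_cfg=loss_cfg, net_cfg=net_cfg,
                            **config.get("train", {}))
    ds_cfg = config.get("dataset", {})
    return seed, sub, spec, art, net_cfg, train_cfg, extractor, ds_cfg


def run_experiment(config: dict | str, out_dir) -> dict:
    """Simulate -> train -> correct -> evaluate, writing all artifacts.

    `config` is a dict or a path to a YAML file with optional sections
    phantom / artifact / network / loss / extractor / train / dataset
    and a master `seed`.  Returns paths and headline numbers.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(str(config)) as fh:
            config = yaml.safe_load(fh)
    try:
        seed, sub, spec, art, net_cfg, train_cfg, extractor, ds_cfg = \
            _build_from_config(config)
    except TypeError as exc:
        raise ValueError(f"invalid experiment config: {exc}") from exc

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    ds = make_dataset(int(ds_cfg.get("n_train", 8)), int(ds_cfg.get("n_test", 4)),
                      spec, art, sub["data"])
    write_dataset(ds, os.path.join(out_dir, "dataset"))

    model = FfrnModel(net_cfg)
    model, log = train(model, ds, train_cfg, extractor)
    log.write(os.path.join(out_dir, "train_log.tsv"))
    save_checkpoint(model, os.path.join(out_dir, "model.npz"))

    corrected_dir = os.path.join(out_dir, "corrected")
    os.makedirs(corrected_dir, exist_ok=True)
    for k, img in enumerate(ds.test_cbct):
        out = from_unit_range(model.correct(to_unit_range(img)), img)
        write_raw(out, os.path.join(corrected_dir, f"test_corrected_{k:04d}.raw"))

    rois = [roi_masks(spec, s) for s in ds.test_anatomy_seeds]
    report = evaluate_pairs(model, list(zip(ds.test_cbct, ds.test_ct)), rois)
    report_text = format_report(report)
    with open(os.path.join(out_dir, "report.tsv"), "w") as fh:
        fh.write(report_text)

    return {
        "out_dir": out_dir,
        "report": report,
        "report_text": report_text,
        "log": log,
        "model": model,
        "dataset": ds,
        "input_psnr": report.input.psnr,
        "corrected_psnr": report.corrected.psnr,
    }
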