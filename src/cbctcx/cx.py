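"""Contextual (CX) similarity and loss between deep feature sets.

Given two equal-size feature sets S = {s_i} and T = {t_j} (one vector
per spatial location of an extractor layer), the chain is:

1. centered cosine distances  d_ij = 1 - <s_i - eta_t, t_j - eta_t> /
   (||s_i - eta_t|| ||t_j - eta_t||), with eta_t the mean of T used to
   center BOTH sets;
2. row-normalized distances   d~_ij = d_ij / (min_k d_ik + eps);
3. bandwidth weights          w_ij = exp((1 - d~_ij)/h);
4. row-normalized similarity  CX_ij = w_ij / sum_k w_ik  (each row of
   the matrix sums to one, and the map is invariant to per-row positive
   rescaling of w);
5. image similarity           CX(S,T) = mean_j max_i CX_ij, a scalar in
   (0, 1] that equals 1 when T = S (up to the eps perturbation);
6. loss                       L_CX = log(1 / CX(S,T)).

The combined unpaired objective for a generator output G(s) is
``L = lambda * L_CX(G(s), t, l_style) + L_CX(G(s), s, l_content)`` with
the style term taken against a CT-domain image t and the content term
against the CBCT input s; multiple style/content layers are averaged
with equal weight.  Defaults: h = 0.5, eps = 1e-5, lambda = 5.

Every public operation is a thin numpy wrapper over a differentiable
tensor path, so training uses exactly the code the oracle tests check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, take_rows
from .features import FeatureSet, FeatureExtractor, equalize_sizes, sample_indices

__all__ = [
    "CxMatrices",
    "LossConfig",
    "centered_cosine_distance",
    "normalize_distances",
    "weights_from_distances",
    "contextual_matrix",
    "image_similarity",
    "compute_cx_matrices",
    "cx_similarity",
    "cx_loss",
    "combined_loss",
    "cx_loss_tensor",
    "combined_loss_tensor",
]


@dataclass
class CxMatrices:
    """The four N x N grids of the contextual-similarity chain."""

    d: np.ndarray
    d_norm: np.ndarray
    w: np.ndarray
    cx: np.ndarray


@dataclass
class LossConfig:
    h: float = 0.5
    epsilon: float = 1e-5
    lambda_weight: float = 5.0
    content_layers: tuple[str, ...] = ("conv4_2",)
    style_layers: tuple[str, ...] = ("conv3_2", "conv4_2")
    sample_n: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("bandwidth h must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be non-negative")
        if self.sample_n < 1:
            raise ValueError("sample_n must be at least 1")


def _vectors(x) -> np.ndarray:
    if isinstance(x, FeatureSet):
        return x.vectors
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"feature set must be 2-D (N, D), got shape {arr.shape}")
    return arr


# -- differentiable tensor path ---------------------------------------------

def _distances_t(S: Tensor, T: Tensor) -> Tensor:
    if S.shape[0] != T.shape[0]:
        raise ValueError(f"|S|={S.shape[0]} and |T|={T.shape[0]} differ; "
                         "sample the larger set first")
    eta = T.mean(axis=0, keepdims=True)
    Sc = S - eta
    Tc = T - eta
    sn = (Sc * Sc).sum(axis=1, keepdims=True).sqrt()
    tn = (Tc * Tc).sum(axis=1, keepdims=True).sqrt()
    for label, norms in (("s", sn.data), ("t", tn.data)):
        bad = np.nonzero(norms.ravel() == 0)[0]
        if bad.size:
            raise ValueError(
                f"centered feature vector {label}[{int(bad[0])}] has zero norm; "
                "constant inputs must be jittered before the contextual loss")
    d = 1.0 - (Sc / sn) @ (Tc / tn).T
    return d.relu()     # clamp negative round-off to 0


def _normalized_t(d: Tensor, epsilon: float) -> Tensor:
    dmin = d.min(axis=1, keepdims=True)
    return d / (dmin + epsilon)


def _cx_from_normalized_t(d_norm: Tensor, h: float) -> Tensor:
    # softmax of (1 - d~)/h, computed with a per-row shift so extreme
    # bandwidths cannot overflow; row-constant shifts cancel in Eq-style
    # row normalization.
    z = (1.0 - d_norm) * (1.0 / h)
    z = z - z.max(axis=1, keepdims=True).detach()
    w = z.exp()
    return w / w.sum(axis=1, keepdims=True)


def _similarity_t(cx: Tensor) -> Tensor:
    return cx.max(axis=0).mean()


def cx_similarity_tensor(S: Tensor, T: Tensor, h: float = 0.5,
                         epsilon: float = 1e-5) -> Tensor:
    d = _distances_t(S, T)
    return _similarity_t(_cx_from_normalized_t(_normalized_t(d, epsilon), h))


# -- public numpy operations -------------------------------------------------

def centered_cosine_distance(S, T) -> np.ndarray:
    """N x N centered cosine distances; both sets centered by mean(T)."""
    return _distances_t(Tensor(_vectors(S)), Tensor(_vectors(T))).data


def normalize_distances(d: np.ndarray, epsilon: float = 1e-5) -> np.ndarray:
    """Divide each row by its minimum plus epsilon."""
    d = np.maximum(np.asarray(d, dtype=np.float64), 0.0)
    return _normalized_t(Tensor(d), epsilon).data


def weights_from_distances(d_norm: np.ndarray, h: float = 0.5) -> np.ndarray:
    """w_ij = exp((1 - d~_ij)/h); mathematically strictly positive and
    decreasing in d~.  Extremely dissimilar pairs can underflow to 0.0 in
    float64; every row keeps its O(1) entry at the row minimum, so the
    downstream row normalization is unaffected (the pipeline itself uses
    a row-shifted exponent and never overflows or divides by zero)."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    return np.exp((1.0 - np.asarray(d_norm, dtype=np.float64)) / h)


def contextual_matrix(w: np.ndarray) -> np.ndarray:
    """Row-normalize the weight grid so every row sums to one."""
    w = np.asarray(w, dtype=np.float64)
    return w / w.sum(axis=1, keepdims=True)


def image_similarity(cx: np.ndarray) -> float:
    """Mean over columns j of the column-wise maximum over i."""
    cx = np.asarray(cx, dtype=np.float64)
    return float(cx.max(axis=0).mean())


def compute_cx_matrices(S, T, cfg: LossConfig | None = None) -> CxMatrices:
    cfg = cfg or LossConfig()
    d = centered_cosine_distance(S, T)
    d_norm = normalize_distances(d, cfg.epsilon)
    w = weights_from_distances(d_norm, cfg.h)
    return CxMatrices(d=d, d_norm=d_norm, w=w, cx=contextual_matrix(w))


def cx_similarity(S, T, h: float = 0.5, epsilon: float = 1e-5) -> float:
    """The full chain: distances -> normalization -> weights -> CX(S,T)."""
    return float(cx_similarity_tensor(Tensor(_vectors(S)), Tensor(_vectors(T)),
                                      h=h, epsilon=epsilon).data)


# -- image-level losses ------------------------------------------------------

def _features_for(img: np.ndarray, layer: str, extractor: FeatureExtractor,
                  cfg: LossConfig) -> FeatureSet:
    return extractor.extract(img, [layer])[layer]


def cx_loss(s_img: np.ndarray, t_img: np.ndarray, layer: str,
            extractor: FeatureExtractor, cfg: LossConfig | None = None) -> float:
    """log(1 / CX) between one layer's feature sets of two images."""
    cfg = cfg or LossConfig()
    fs = _features_for(s_img, layer, extractor, cfg)
    ft = _features_for(t_img, layer, extractor, cfg)
    fs, ft = equalize_sizes(fs, ft, cfg.seed, cap=cfg.sample_n)
    return float(-np.log(cx_similarity(fs, ft, h=cfg.h, epsilon=cfg.epsilon)))


def combined_loss(g_out: np.ndarray, s_img: np.ndarray, t_img: np.ndarray,
                  extractor: FeatureExtractor, cfg: LossConfig | None = None) -> float:
    """lambda * style term (against t over style layers) + content term
    (against s over content layers); multiple layers averaged equally."""
    cfg = cfg or LossConfig()
    style = np.mean([cx_loss(g_out, t_img, l, extractor, cfg) for l in cfg.style_layers])
    content = np.mean([cx_loss(g_out, s_img, l, extractor, cfg) for l in cfg.content_layers])
    return float(cfg.lambda_weight * style + content)


# -- differentiable losses for training -------------------------------------

def _sampled_pair_loss(g_feat: Tensor, target: np.ndarray, cfg: LossConfig,
                       seed: int) -> Tensor:
    """-log CX between a differentiable feature tensor and a fixed target
    feature array, both sampled to a common size."""
    n_g, n_t = g_feat.shape[0], target.shape[0]
    n = min(n_g, n_t, cfg.sample_n)
    same = n_g == n_t
    if n_g > n:
        g_feat = take_rows(g_feat, sample_indices(n_g, n, seed))
    if n_t > n:
        target = target[sample_indices(n_t, n, seed if same else seed + 1)]
    sim = cx_similarity_tensor(g_feat, Tensor(target), h=cfg.h, epsilon=cfg.epsilon)
    return -(sim.log())


def cx_loss_tensor(g_feats: dict[str, Tensor], target_feats: dict[str, np.ndarray],
                   layers, cfg: LossConfig, seed: int) -> Tensor:
    terms = [_sampled_pair_loss(g_feats[l], target_feats[l], cfg, seed + 17 * i)
             for i, l in enumerate(layers)]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def combined_loss_tensor(g_feats: dict[str, Tensor],
                         s_feats: dict[str, np.ndarray],
                         t_feats: dict[str, np.ndarray],
                         cfg: LossConfig, seed: int = 0) -> tuple[Tensor, float, float]:
    """Differentiable combined objective; returns (loss, style, content)."""
    style = cx_loss_tensor(g_feats, t_feats, cfg.style_layers, cfg, seed)
    content = cx_loss_tensor(g_feats, s_feats, cfg.content_layers, cfg, seed + 1009)
    loss = style * cfg.lambda_weight + content
    return loss, float(style.data), float(content.data)
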