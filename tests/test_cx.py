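"""Contextual-similarity chain: printed examples, brute-force oracle
equivalence and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctcx.cx import (LossConfig, centered_cosine_distance, combined_loss,
                       compute_cx_matrices, contextual_matrix, cx_loss,
                       cx_similarity, image_similarity, normalize_distances,
                       weights_from_distances)
from cbctcx.features import FeatureExtractor

from conftest import cx_chain_oracle


def test_distance_of_aligned_and_opposed_vectors():
    T = np.array([[1.0, 0.0], [-1.0, 0.0]])
    d = centered_cosine_distance(T, T)
    np.testing.assert_allclose(d, [[0.0, 2.0], [2.0, 0.0]], atol=1e-12)


def test_distance_diagonal_is_zero_for_identical_sets(rng):
    S = rng.standard_normal((10, 4))
    np.testing.assert_allclose(np.diag(centered_cosine_distance(S, S)), 0.0,
                               atol=1e-12)


def test_distance_rejects_zero_norm_centered_vector():
    # the middle target vector coincides with the target mean exactly
    T = np.array([[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0]])
    with pytest.raises(ValueError, match=r"\[1\] has zero norm"):
        centered_cosine_distance(T, T)


def test_normalize_distances_examples():
    np.testing.assert_allclose(normalize_distances(np.array([[0.0, 2.0]]), 1e-5),
                               [[0.0, 200000.0]])
    out = normalize_distances(np.array([[3.0, 3.0]]), 1e-5)
    assert (out < 1).all() and np.allclose(out, 3.0 / (3.0 + 1e-5))


def test_weights_examples_and_monotonicity(rng):
    assert weights_from_distances(np.array([[1.0]]), h=0.5) == 1.0
    np.testing.assert_allclose(weights_from_distances(np.array([[0.0]]), h=0.5),
                               np.e ** 2)
    dn = np.sort(rng.random((1, 10)))
    w = weights_from_distances(dn, h=0.5)
    assert (np.diff(w[0]) < 0).all()


def test_contextual_matrix_examples():
    np.testing.assert_allclose(contextual_matrix(np.array([[1.0, 1.0]])), [[0.5, 0.5]])
    np.testing.assert_allclose(contextual_matrix(np.array([[2.0, 6.0]])), [[0.25, 0.75]])


def test_image_similarity_examples(rng):
    n = 6
    assert image_similarity(np.eye(n)) == pytest.approx(1.0)
    assert image_similarity(np.full((n, n), 1.0 / n)) == pytest.approx(1.0 / n)


@pytest.mark.parametrize("seed", range(10))
def test_full_chain_matches_scalar_oracle(seed):
    """Vectorized Eqs-chain equals the pure-Python double-loop oracle."""
    rng = np.random.default_rng(seed)
    N = int(rng.integers(3, 17))
    D = int(rng.integers(2, 9))
    S = rng.standard_normal((N, D))
    T = rng.standard_normal((N, D))
    m = compute_cx_matrices(S, T)
    d_o, dn_o, w_o, cx_o, CX_o = cx_chain_oracle(S, T)
    np.testing.assert_allclose(m.d, d_o, atol=1e-10)
    np.testing.assert_allclose(m.d_norm, dn_o, atol=1e-10)
    np.testing.assert_allclose(m.w, w_o, atol=1e-10)
    np.testing.assert_allclose(m.cx, cx_o, atol=1e-12)
    assert cx_similarity(S, T) == pytest.approx(CX_o, abs=1e-12)


def test_self_similarity_is_one(rng):
    """CX(S, S) = 1: a set compared with itself is maximally similar."""
    S = rng.standard_normal((64, 32))
    assert abs(cx_similarity(S, S) - 1.0) < 1e-3


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 12), st.integers(2, 6))
def test_cx_matrix_invariants(seed, n, d):
    rng = np.random.default_rng(seed)
    m = compute_cx_matrices(rng.standard_normal((n, d)), rng.standard_normal((n, d)))
    assert (m.d >= 0).all() and (m.d <= 2 + 1e-9).all()
    assert (m.d_norm >= 0).all()
    assert (m.d_norm.min(axis=1) <= 1 + 1e-12).all()
    # w is mathematically positive; float64 may underflow far-off entries,
    # but every row keeps its O(1) weight at the row-minimum distance
    assert (m.w >= 0).all() and (m.w.max(axis=1) > 0).all()
    np.testing.assert_allclose(m.cx.sum(axis=1), 1.0, atol=1e-12)


def test_row_rescaling_leaves_cx_unchanged(rng):
    w = np.exp(rng.standard_normal((7, 7)))
    scale = rng.uniform(0.1, 10.0, size=(7, 1))
    np.testing.assert_allclose(contextual_matrix(w * scale), contextual_matrix(w),
                               atol=1e-12)


def test_permutation_invariance_of_similarity(rng):
    S = rng.standard_normal((12, 5))
    T = rng.standard_normal((12, 5))
    base = cx_similarity(S, T)
    for _ in range(3):
        ps = rng.permutation(12)
        pt = rng.permutation(12)
        assert cx_similarity(S[ps], T[pt]) == pytest.approx(base, abs=1e-12)


def test_extreme_bandwidth_does_not_overflow(rng):
    S = rng.standard_normal((8, 4))
    T = rng.standard_normal((8, 4))
    val = cx_similarity(S, T, h=1e-4)
    assert np.isfinite(val) and 0 < val <= 1


# -- image-level losses ------------------------------------------------------

@pytest.fixture(scope="module")
def extractor():
    return FeatureExtractor(seed=0, width_scale=0.25)


@pytest.fixture(scope="module")
def cfg():
    return LossConfig(sample_n=128)


def test_loss_is_zero_for_identical_images(extractor, cfg, rng):
    img = rng.random((32, 32))
    assert cx_loss(img, img, "conv2_2", extractor, cfg) < 1e-3


def test_loss_equals_log_n_for_uniform_similarity():
    n = 16
    assert -np.log(image_similarity(np.full((n, n), 1.0 / n))) == pytest.approx(np.log(n))


def test_loss_matches_brute_force_oracle(extractor, rng):
    """Image-level loss agrees with -log(CX) computed by the scalar oracle
    on the same (sampled) feature sets."""
    cfg = LossConfig(sample_n=16, seed=4)
    a, b = rng.random((16, 16)), rng.random((16, 16))
    loss = cx_loss(a, b, "conv2_2", extractor, cfg)
    from cbctcx.features import equalize_sizes
    fa = extractor.extract(a, ["conv2_2"])["conv2_2"]
    fb = extractor.extract(b, ["conv2_2"])["conv2_2"]
    fa, fb = equalize_sizes(fa, fb, cfg.seed, cap=cfg.sample_n)
    *_, CX = cx_chain_oracle(fa.vectors, fb.vectors)
    assert loss == pytest.approx(-np.log(CX), abs=1e-10)


def test_combined_loss_composes_single_layer_terms(extractor, cfg, rng):
    g, s, t = (rng.random((32, 32)) for _ in range(3))
    style = np.mean([cx_loss(g, t, l, extractor, cfg) for l in cfg.style_layers])
    content = np.mean([cx_loss(g, s, l, extractor, cfg) for l in cfg.content_layers])
    total = combined_loss(g, s, t, extractor, cfg)
    assert total == pytest.approx(cfg.lambda_weight * style + content, abs=1e-10)
    assert total == pytest.approx(5.0 * style + content, abs=1e-10)


def test_zero_lambda_identity_output_gives_zero_loss(extractor, rng):
    cfg0 = LossConfig(lambda_weight=0.0, sample_n=128)
    s = rng.random((32, 32))
    t = rng.random((32, 32))
    assert combined_loss(s, s, t, extractor, cfg0) < 1e-3


def test_loss_config_validation():
    for bad in (dict(h=0.0), dict(epsilon=0.0), dict(lambda_weight=-1.0),
                dict(sample_n=0)):
        with pytest.raises(ValueError):
            LossConfig(**bad)
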