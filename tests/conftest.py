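"""Shared fixtures and independent scalar oracles.

The oracles deliberately use pure-Python double loops (no vectorized
numpy) so they stay independent of the implementation paths they check.
"""

import math

import numpy as np
import pytest


def cx_chain_oracle(S, T, eps=1e-5, h=0.5):
    """Brute-force contextual-similarity chain on plain nested lists.

    Returns (d, d_norm, w, cx, CX) where the grids are lists of lists.
    """
    S = [list(map(float, row)) for row in S]
    T = [list(map(float, row)) for row in T]
    N, D = len(S), len(S[0])
    eta = [sum(T[j][k] for j in range(N)) / N for k in range(D)]
    Sc = [[S[i][k] - eta[k] for k in range(D)] for i in range(N)]
    Tc = [[T[j][k] - eta[k] for k in range(D)] for j in range(N)]
    d = [[0.0] * N for _ in range(N)]
    for i in range(N):
        for j in range(N):
            dot = sum(Sc[i][k] * Tc[j][k] for k in range(D))
            ns = math.sqrt(sum(v * v for v in Sc[i]))
            nt = math.sqrt(sum(v * v for v in Tc[j]))
            d[i][j] = max(1.0 - dot / (ns * nt), 0.0)
    d_norm = [[0.0] * N for _ in range(N)]
    for i in range(N):
        dmin = min(d[i])
        for j in range(N):
            d_norm[i][j] = d[i][j] / (dmin + eps)
    w = [[math.exp((1.0 - d_norm[i][j]) / h) for j in range(N)] for i in range(N)]
    cx = [[0.0] * N for _ in range(N)]
    for i in range(N):
        row = sum(w[i])
        for j in range(N):
            cx[i][j] = w[i][j] / row
    CX = sum(max(cx[i][j] for i in range(N)) for j in range(N)) / N
    return d, d_norm, w, cx, CX


def conv2d_oracle(x, w, b):
    """Scalar same-padding stride-1 convolution (cross-correlation)."""
    C_in, H, W = x.shape
    C_out, _, k, _ = w.shape
    p = k // 2
    out = np.zeros((C_out, H, W))
    for o in range(C_out):
        for y in range(H):
            for z in range(W):
                acc = b[o]
                for c in range(C_in):
                    for dy in range(k):
                        for dz in range(k):
                            yy, zz = y + dy - p, z + dz - p
                            if 0 <= yy < H and 0 <= zz < W:
                                acc += w[o, c, dy, dz] * x[c, yy, zz]
                out[o, y, z] = acc
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    from cbctcx.phantom import PhantomSpec
    return PhantomSpec(size=64)
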