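"""Shared fixtures: independent brute-force oracles for the texture features.

The oracles evaluate the defining sums with explicit Python loops, staying
deliberately independent of the vectorized implementations they check.
"""

import math

import numpy as np
import pytest


def _naive_fos(pixels):
    """Population moments by explicit double loop."""
    vals = [float(v) for row in np.asarray(pixels) for v in row]
    n = len(vals)
    mu = sum(vals) / n
    var = sum((v - mu) ** 2 for v in vals) / n
    std = math.sqrt(var)
    if std == 0:
        return mu, std, float("nan"), float("nan")
    skew = (sum((v - mu) ** 3 for v in vals) / n) / std**3
    kurt = (sum((v - mu) ** 4 for v in vals) / n) / var**2
    return mu, std, skew, kurt


def _naive_glcm(pixels, n_levels, distance, directions, symmetric):
    """Pair enumeration by explicit loops over every pixel and offset."""
    x = np.asarray(pixels, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        levels = np.zeros(x.shape, dtype=int)
    else:
        levels = np.minimum(
            ((x - lo) / (hi - lo) * n_levels).astype(int), n_levels - 1
        )
    offs = {
        0.0: (0, distance),
        45.0: (-distance, distance),
        90.0: (-distance, 0),
        135.0: (-distance, -distance),
    }
    h, w = levels.shape
    counts = [[0.0] * n_levels for _ in range(n_levels)]
    for angle in directions:
        dr, dc = offs[float(angle) % 180.0]
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[levels[r, c]][levels[r2, c2]] += 1.0
    if symmetric:
        counts = [
            [counts[i][j] + counts[j][i] for j in range(n_levels)]
            for i in range(n_levels)
        ]
    total = sum(sum(row) for row in counts)
    return np.array([[v / total for v in row] for row in counts])


def _naive_sos(p):
    """The five GLCM features by explicit double loops over levels."""
    n = p.shape[0]
    pi = [sum(p[i][j] for j in range(n)) for i in range(n)]
    pj = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_i = sum(i * pi[i] for i in range(n))
    mu_j = sum(j * pj[j] for j in range(n))
    s_i = math.sqrt(sum((i - mu_i) ** 2 * pi[i] for i in range(n)))
    s_j = math.sqrt(sum((j - mu_j) ** 2 * pj[j] for j in range(n)))
    energy = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    inertia = sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    entropy = -sum(
        p[i][j] * math.log(p[i][j])
        for i in range(n)
        for j in range(n)
        if p[i][j] > 0
    )
    if s_i == 0 or s_j == 0:
        corr = 0.0
    else:
        corr = sum(
            (i - mu_i) * (j - mu_j) * p[i][j] for i in range(n) for j in range(n)
        ) / (s_i * s_j)
    return energy, inertia, corr, idm, entropy


@pytest.fixture(scope="session")
def naive_fos():
    return _naive_fos


@pytest.fixture(scope="session")
def naive_glcm():
    return _naive_glcm


@pytest.fixture(scope="session")
def naive_sos():
    return _naive_sos
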