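"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity along a different code path from the
package: explicit kernel construction and literal formulas instead of
scipy.ndimage pipelines, full enumeration instead of closed-form
distributions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


# -- Frangi vesselness, literal formula with explicit convolutions ---------


def _gaussian_derivative_kernel(sigma: float, order: int, truncate: float = 4.0):
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        return -x / sigma**2 * g
    if order == 2:
        return (x**2 / sigma**4 - 1.0 / sigma**2) * g
    raise ValueError(order)


def _conv_separable(img: np.ndarray, ky: np.ndarray, kx: np.ndarray) -> np.ndarray:
    ry, rx = len(ky) // 2, len(kx) // 2
    padded = np.pad(img, ((ry, ry), (rx, rx)), mode="symmetric")
    tmp = np.apply_along_axis(lambda col: np.convolve(col, ky, mode="valid"), 0, padded)
    return np.apply_along_axis(lambda row: np.convolve(row, kx, mode="valid"), 1, tmp)


def frangi_bruteforce(img, scales=(1.0, 2.0), beta=0.5, c="auto"):
    """Bright-vessel multiscale vesselness from first principles."""
    img = np.asarray(img, dtype=float)
    img = img - img.mean()
    out = np.zeros_like(img)
    for s in scales:
        k0 = _gaussian_derivative_kernel(s, 0)
        k1 = _gaussian_derivative_kernel(s, 1)
        k2 = _gaussian_derivative_kernel(s, 2)
        hyy = s * s * _conv_separable(img, k2, k0)
        hxx = s * s * _conv_separable(img, k0, k2)
        hxy = s * s * _conv_separable(img, k1, k1)
        v = np.zeros_like(img)
        smax = 0.0
        lam1 = np.empty_like(img)
        lam2 = np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                H = np.array([[hyy[i, j], hxy[i, j]], [hxy[i, j], hxx[i, j]]])
                evals = np.linalg.eigvalsh(H)
                a, b = sorted(evals, key=abs)
                lam1[i, j], lam2[i, j] = a, b
                smax = max(smax, math.hypot(a, b))
        c_s = 0.5 * smax if c == "auto" else float(c)
        if c_s <= 0:
            continue
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                l1, l2 = lam1[i, j], lam2[i, j]
                if l2 > 0:
                    continue
                S = math.hypot(l1, l2)
                rb2 = (l1 / l2) ** 2 if l2 != 0 else 0.0
                v[i, j] = math.exp(-rb2 / (2 * beta**2)) * (
                    1.0 - math.exp(-(S**2) / (2 * c_s**2))
                )
        out = np.maximum(out, v)
    return np.clip(out, 0.0, 1.0)


# -- Wilcoxon signed-rank: full 2^n sign enumeration ------------------------


def wilcoxon_exact_enumeration(differences) -> float:
    """Two-sided p by enumerating all 2^n equiprobable sign assignments."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    dev_obs = abs(w_obs - center)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= dev_obs - 1e-12:
            hits += 1
    return hits / 2**n


# -- Friedman: within-block permutation enumeration -------------------------


def friedman_reference_statistic(matrix) -> float:
    """Tie-corrected Friedman chi-square, written out longhand."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = np.array([rankdata(row) for row in m])
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in m:
        for t in np.unique(row, return_counts=True)[1]:
            tie_term += t**3 - t
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0:
        return 0.0
    return chisq / correction


def friedman_permutation_p(matrix) -> float:
    """Exact p: all (k!)^n within-block permutations of the observed values."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    obs = friedman_reference_statistic(m)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.array([m[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman_reference_statistic(permuted) >= obs - 1e-9:
            hits += 1
    return hits / total
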