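"""Numba-compiled inner loops for the template-matching entropies.

These are O(N^2 * m) pairwise scans over embedded templates with Chebyshev
distance. They are deliberately plain loops: numba compiles them to machine
code, and the pure-Python brute-force references used in the test suite share
no code with them.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def apen_kernel(x: np.ndarray, m: int, r: float) -> float:
    """Pincus ApEn: phi^m - phi^{m+1}, self-matches included, natural log."""
    n = x.shape[0]
    nm = n - m + 1  # number of length-m templates
    nm1 = n - m  # number of length-(m+1) templates
    cm = np.ones(nm, dtype=np.int64)  # self-matches
    cm1 = np.ones(nm1, dtype=np.int64)
    for i in range(nm):
        for j in range(i + 1, nm):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                cm[i] += 1
                cm[j] += 1
                if j < nm1 and abs(x[i + m] - x[j + m]) <= r:
                    cm1[i] += 1
                    cm1[j] += 1
    phim = 0.0
    for i in range(nm):
        phim += np.log(cm[i] / nm)
    phim1 = 0.0
    for i in range(nm1):
        phim1 += np.log(cm1[i] / nm1)
    return phim / nm - phim1 / nm1


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple:
    """Sample-entropy pair counts (A, B): matches at m+1 and at m.

    Both counts run over the first N-m templates (i < j), self-matches
    excluded.
    """
    n = x.shape[0]
    M = n - m
    A = 0
    B = 0
    for i in range(M):
        for j in range(i + 1, M):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B


@njit(cache=True)
def lz76_kernel(s: np.ndarray) -> int:
    """Lempel-Ziv-76 phrase count of a binary sequence (Kaspar-Schuster scan)."""
    n = s.shape[0]
    c = 1
    l = 1
    i = 0
    k = 1
    kmax = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


@njit(cache=True)
def fuzzen_kernel(x: np.ndarray, m: int, r: float, n_pow: float) -> float:
    """Chen's fuzzy entropy: mean exponential membership of baseline-removed
    template distances, ln(phi^m) - ln(phi^{m+1})."""
    n = x.shape[0]
    M = n - m  # templates for both lengths
    mu_m = np.empty(M)
    mu_m1 = np.empty(M)
    for i in range(M):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        mu_m[i] = s / m
        mu_m1[i] = (s + x[i + m]) / (m + 1)
    phim = 0.0
    phim1 = 0.0
    square = n_pow == 2.0  # avoid the generic pow in the common case
    if square:
        for i in range(M):
            for j in range(i + 1, M):
                d = 0.0
                for k in range(m):
                    t = abs((x[i + k] - mu_m[i]) - (x[j + k] - mu_m[j]))
                    if t > d:
                        d = t
                u = d / r
                phim += np.exp(-(u * u))
                d = 0.0
                for k in range(m + 1):
                    t = abs((x[i + k] - mu_m1[i]) - (x[j + k] - mu_m1[j]))
                    if t > d:
                        d = t
                u = d / r
                phim1 += np.exp(-(u * u))
    else:
        for i in range(M):
            for j in range(i + 1, M):
                d = 0.0
                for k in range(m):
                    t = abs((x[i + k] - mu_m[i]) - (x[j + k] - mu_m[j]))
                    if t > d:
                        d = t
                phim += np.exp(-((d / r) ** n_pow))
                d = 0.0
                for k in range(m + 1):
                    t = abs((x[i + k] - mu_m1[i]) - (x[j + k] - mu_m1[j]))
                    if t > d:
                        d = t
                phim1 += np.exp(-((d / r) ** n_pow))
    pairs = M * (M - 1) / 2.0
    return np.log(phim / pairs) - np.log(phim1 / pairs)
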