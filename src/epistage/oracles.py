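"""Slow, literal reference implementations of the complexity measures.

Each function here transcribes the defining formula as plain Python loops,
independently of the fast kernels in :mod:`epistage.complexity`. They exist to
cross-check the fast path (the test suite asserts agreement on random inputs)
and as executable documentation of the definitions. Complexity is O(N^2) or
worse — use them only on short sequences.
"""

from __future__ import annotations

import math
from typing import Sequence

__all__ = [
    "apen_bruteforce",
    "sampen_bruteforce",
    "pe_bruteforce",
    "fuzzen_bruteforce",
    "lz76_bruteforce",
]


def _cheb(x: Sequence[float], i: int, j: int, m: int) -> float:
    return max(abs(x[i + k] - x[j + k]) for k in range(m))


def apen_bruteforce(x: Sequence[float], m: int, r: float) -> float:
    x = list(map(float, x))
    N = len(x)

    def phi(mm: int) -> float:
        M = N - mm + 1
        total = 0.0
        for i in range(M):
            count = 0
            for j in range(M):
                if _cheb(x, i, j, mm) <= r:
                    count += 1
            total += math.log(count / M)
        return total / M

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x: Sequence[float], m: int, r: float) -> float:
    x = list(map(float, x))
    N = len(x)
    M = N - m
    B = sum(
        1
        for i in range(M)
        for j in range(M)
        if i != j and _cheb(x, i, j, m) <= r
    )
    A = sum(
        1
        for i in range(M)
        for j in range(M)
        if i != j and _cheb(x, i, j, m + 1) <= r
    )
    if B == 0:
        raise ArithmeticError("no matches at length m")
    if A == 0:
        return math.inf
    return -math.log(A / B)


def pe_bruteforce(
    x: Sequence[float], order: int, delay: int, normalize: bool
) -> float:
    x = list(map(float, x))
    n_patterns = len(x) - (order - 1) * delay
    counts: dict[tuple, int] = {}
    for start in range(n_patterns):
        window = [x[start + delay * k] for k in range(order)]
        # rank positions by value, earlier index first on ties
        pattern = tuple(
            sorted(range(order), key=lambda k: (window[k], k))
        )
        counts[pattern] = counts.get(pattern, 0) + 1
    # accumulate in lexicographic pattern order (a canonical summation order)
    h = 0.0
    for pattern in sorted(counts):
        p = counts[pattern] / n_patterns
        h -= p * math.log(p)
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def fuzzen_bruteforce(x: Sequence[float], m: int, r: float, n: float) -> float:
    x = list(map(float, x))
    N = len(x)
    M = N - m

    def phi(mm: int) -> float:
        templates = []
        for i in range(M):
            t = [x[i + k] for k in range(mm)]
            mu = sum(t) / mm
            templates.append([v - mu for v in t])
        total = 0.0
        pairs = 0
        for i in range(M):
            for j in range(M):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                total += math.exp(-((d / r) ** n))
                pairs += 1
        return total / pairs

    return math.log(phi(m)) - math.log(phi(m + 1))


def lz76_bruteforce(bits: Sequence[int]) -> int:
    """Exhaustive-history LZ76 parse by literal substring search.

    Each phrase is the shortest prefix of the remaining string that does not
    occur inside the history extended by the phrase minus its last symbol.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    p = 0
    while p < n:
        l = 1
        while p + l <= n and s[p : p + l] in s[: p + l - 1]:
            l += 1
        c += 1
        p += l
    return c
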