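"""Five nonlinear complexity measures for 1-D signals.

The measures quantify how irregular / unpredictable a time series is:

* **ApEn** (approximate entropy, Pincus): difference between the log
  probability that templates of length ``m`` match (Chebyshev distance within
  ``r``, self-matches included) and the same at length ``m+1``.
* **SampEn** (sample entropy, Richman & Moorman): ``-ln(A/B)`` where ``B``
  and ``A`` count matching template *pairs* at lengths ``m`` and ``m+1``,
  self-matches excluded.
* **PE** (permutation entropy, Bandt & Pompe): Shannon entropy of the
  empirical distribution of ordinal (rank-order) patterns of embedded
  subsequences.
* **FuzzEn** (fuzzy entropy, Chen): SampEn-like, but with baseline-removed
  templates and a smooth exponential membership ``exp(-(d/r)^n)`` in place of
  the hard threshold.
* **KC** (Kolmogorov complexity, operationalized): Lempel-Ziv-76 phrase count
  of the median-binarized signal, optionally normalized by ``log2(n)/n``.

All logarithms are natural except the LZ normalization. Tolerances ``r`` are
absolute here; :func:`extract_features` scales ``r_frac`` by each channel's
standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import apen_kernel, fuzzen_kernel, lz76_kernel, sampen_counts
from .preprocess import Epoch
from .signal_io import Stage

__all__ = [
    "MEASURE_NAMES",
    "ComplexityParams",
    "FeatureMatrix",
    "UndefinedResultError",
    "approx_entropy",
    "sample_entropy",
    "permutation_entropy",
    "fuzzy_entropy",
    "kolmogorov_complexity",
    "extract_features",
]

#: Column order of every feature matrix produced by this package.
MEASURE_NAMES = ["ApEn", "SampEn", "PE", "FuzzEn", "KC"]


class UndefinedResultError(ArithmeticError):
    """The statistic is undefined on this input (e.g. SampEn with no m-matches)."""


@dataclass(frozen=True)
class ComplexityParams:
    """Parameters of the five measures.

    Defaults are the dominant conventions in the EEG-entropy literature:
    embedding dimension 2 with tolerance 0.2 x SD for the template entropies,
    order-3 delay-1 ordinal patterns, fuzzy exponent 2, and normalized PE/KC.
    ``sampen_cap`` replaces SampEn's +inf sentinel (zero matches at ``m+1``)
    inside feature matrices so they stay finite.
    """

    m_embed: int = 2
    r_frac: float = 0.2
    pe_order: int = 3
    pe_delay: int = 1
    fuzz_power: float = 2.0
    pe_normalize: bool = True
    kc_normalize: bool = True
    sampen_cap: float = 10.0

    def __post_init__(self) -> None:
        if self.m_embed < 1:
            raise ValueError("m_embed must be >= 1")
        if not self.r_frac > 0:
            raise ValueError("r_frac must be positive")
        if self.pe_order < 2:
            raise ValueError("pe_order must be >= 2")
        if self.pe_delay < 1:
            raise ValueError("pe_delay must be >= 1")
        if not self.fuzz_power > 0:
            raise ValueError("fuzz_power must be positive")


@dataclass
class FeatureMatrix:
    """Per-epoch complexity features: ``channels x 5`` (ApEn, SampEn, PE, FuzzEn, KC)."""

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    stage: Stage = Stage.UNKNOWN
    subject_id: str = ""
    epoch_index: int = 0
    measure_names: list[str] = field(default_factory=lambda: list(MEASURE_NAMES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(MEASURE_NAMES):
            raise ValueError(
                f"feature matrix must be channels x {len(MEASURE_NAMES)}, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        self.stage = Stage.coerce(self.stage)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _as_1d(x) -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=float).ravel()
    return arr


def approx_entropy(x: Sequence[float], m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy with absolute tolerance ``r`` (Chebyshev distance)."""
    arr = _as_1d(x)
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(arr) <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {len(arr)}")
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    return float(apen_kernel(arr, m, r))


def sample_entropy(x: Sequence[float], m: int = 2, r: float = 0.2) -> float:
    """Sample entropy ``-ln(A/B)``.

    Returns ``+inf`` when no template pair matches at length ``m+1``
    (``A = 0``); raises :class:`UndefinedResultError` when none matches at
    length ``m`` (``B = 0``).
    """
    arr = _as_1d(x)
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(arr) <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {len(arr)}")
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    A, B = sampen_counts(arr, m, r)
    if B == 0:
        raise UndefinedResultError("no template pairs match at length m")
    if A == 0:
        return math.inf
    return float(-np.log(A / B))


def _ordinal_patterns(arr: np.ndarray, order: int, delay: int) -> np.ndarray:
    n_patterns = len(arr) - (order - 1) * delay
    idx = np.arange(n_patterns)[:, None] + delay * np.arange(order)[None, :]
    emb = arr[idx]
    # stable argsort ranks ties by earlier index first
    return np.argsort(emb, axis=1, kind="stable")


def permutation_entropy(
    x: Sequence[float], order: int = 3, delay: int = 1, normalize: bool = True
) -> float:
    """Permutation entropy of order-``order``, delay-``delay`` ordinal patterns.

    Natural-log Shannon entropy of the pattern distribution; with
    ``normalize`` the value is divided by ``ln(order!)`` so it lies in [0, 1].
    """
    arr = _as_1d(x)
    if order < 2:
        raise ValueError("order must be >= 2")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    if len(arr) < (order - 1) * delay + 1:
        raise ValueError(
            f"need at least (order-1)*delay+1={(order - 1) * delay + 1} samples"
        )
    patterns = _ordinal_patterns(arr, order, delay)
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    total = int(counts.sum())
    # scalar log over the (at most order!) unique patterns, summed in the
    # lexicographic pattern order np.unique returns
    h = 0.0
    for cnt in counts:
        p = cnt / total
        h -= p * math.log(p)
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def fuzzy_entropy(
    x: Sequence[float], m: int = 2, r: float = 0.2, n: float = 2.0
) -> float:
    """Fuzzy entropy with exponential membership ``exp(-(d/r)^n)``.

    Templates are mean-subtracted before the Chebyshev distance is taken, so
    the measure ignores local baseline shifts.
    """
    arr = _as_1d(x)
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(arr) <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {len(arr)}")
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    if not n > 0:
        raise ValueError("fuzzy power n must be positive")
    return float(fuzzen_kernel(arr, m, r, float(n)))


def lz76_phrase_count(bits: Sequence[int]) -> int:
    """Lempel-Ziv-76 phrase count via the Kaspar-Schuster scan."""
    s = np.ascontiguousarray(bits, dtype=np.int8)
    if len(s) == 0:
        raise ValueError("empty sequence")
    if len(s) == 1:
        return 1
    return int(lz76_kernel(s))


def kolmogorov_complexity(x: Sequence[float], normalize: bool = True) -> float:
    """Lempel-Ziv complexity of the median-binarized signal.

    Values strictly above the median map to 1, the rest to 0; the LZ76 phrase
    count ``c(n)`` of that binary string is returned, normalized to
    ``c(n) * log2(n) / n`` when requested. An all-equal input binarizes to the
    constant string and yields its (small) parse count rather than an error.
    """
    arr = _as_1d(x)
    if len(arr) < 2:
        raise ValueError("need at least 2 samples")
    bits = (arr > np.median(arr)).astype(np.int8)
    c = lz76_phrase_count(bits)
    if normalize:
        return float(c * math.log2(len(arr)) / len(arr))
    return float(c)


def extract_features(epoch: Epoch, params: ComplexityParams | None = None) -> FeatureMatrix:
    """Compute the 5-column feature matrix of an epoch (one row per channel).

    The template-entropy tolerance is ``params.r_frac`` times each channel's
    own standard deviation. Constant channels (SD = 0) get zero entropies by
    convention. A SampEn of +inf (no matches at ``m+1``) is replaced by
    ``params.sampen_cap`` with a warning so the matrix stays finite.
    """
    params = params or ComplexityParams()
    values = np.empty((epoch.n_channels, len(MEASURE_NAMES)))
    for c in range(epoch.n_channels):
        ch = epoch.data[c]
        sd = float(np.std(ch))
        if sd == 0.0:
            apen = sampen = fuzzen = 0.0
        else:
            r = params.r_frac * sd
            apen = approx_entropy(ch, params.m_embed, r)
            try:
                sampen = sample_entropy(ch, params.m_embed, r)
            except UndefinedResultError:
                sampen = math.inf
            if not math.isfinite(sampen):
                warnings.warn(
                    f"SampEn undefined/infinite on channel {c}; "
                    f"capped at {params.sampen_cap}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                sampen = params.sampen_cap
            fuzzen = fuzzy_entropy(ch, params.m_embed, r, params.fuzz_power)
        pe = permutation_entropy(
            ch, params.pe_order, params.pe_delay, params.pe_normalize
        )
        kc = kolmogorov_complexity(ch, params.kc_normalize)
        values[c] = [apen, sampen, pe, fuzzen, kc]
    return FeatureMatrix(
        values,
        channel_names=list(epoch.channel_names),
        stage=epoch.stage,
        subject_id=epoch.subject_id,
        epoch_index=epoch.index,
    )
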