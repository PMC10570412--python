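"""Statistical comparison of stages: one-way ANOVA, Tukey HSD, PCA scores.

ANOVA and Tukey are implemented from the textbook sums-of-squares and
studentized-range formulas, with :mod:`scipy.stats` supplying only the
distribution functions, so small hand-worked examples check them exactly.
PCA is the correlation-matrix variant (columns standardized), matching how
five-dimensional feature matrices are compressed to two score dimensions for
stage-separation plots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .complexity import FeatureMatrix, MEASURE_NAMES
from .preprocess import Epoch
from .signal_io import Stage

__all__ = [
    "StageGroups",
    "GeneralFeatures",
    "GENERAL_FEATURE_NAMES",
    "one_way_anova",
    "tukey_hsd",
    "pca_scores",
    "general_features",
    "stage_separation_report",
    "StageSeparationReport",
]

GENERAL_FEATURE_NAMES = ["mean", "variance", "maximum", "minimum", "skewness"]

_STAGE_ORDER = [Stage.NORMAL, Stage.ACUTE, Stage.CHRONIC]


@dataclass
class StageGroups:
    """Per-stage pooled values of one measure (epochs x channels flattened)."""

    groups: dict  # Stage -> 1-D array

    def __post_init__(self) -> None:
        coerced = {}
        for key, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float).ravel()
            if len(arr) < 2:
                raise ValueError("each group needs at least 2 values")
            coerced[Stage.coerce(key)] = arr
        if len(coerced) < 2:
            raise ValueError("need at least 2 groups")
        self.groups = coerced

    def in_order(self) -> list[tuple[Stage, np.ndarray]]:
        ordered = [(s, self.groups[s]) for s in _STAGE_ORDER if s in self.groups]
        extras = [
            (s, v) for s, v in self.groups.items() if s not in _STAGE_ORDER
        ]
        return ordered + extras


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, StageGroups):
        return [v for _, v in groups.in_order()]
    return [np.asarray(g, dtype=float).ravel() for g in groups]


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and upper-tail p-value.

    ``F = MSB / MSW`` with ``(k-1, N-k)`` degrees of freedom, where MSB is the
    between-group and MSW the within-group mean square.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(g) for g in gs])
    if (ns < 2).any():
        raise ValueError("each group needs at least 2 values")
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance: F is degenerate")
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    F = msb / msw
    p = float(sps.f.sf(F, k - 1, N - k))
    return F, p


def tukey_hsd(groups) -> list[dict]:
    """Tukey(-Kramer) pairwise comparisons after one-way ANOVA.

    For each pair the studentized-range statistic is
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` and the adjusted
    p-value is its upper tail at ``(k, N-k)``. Mean differences are signed
    first-minus-second in stage order (normal, acute, chronic).
    """
    if isinstance(groups, StageGroups):
        named = groups.in_order()
    else:
        named = [(i, np.asarray(g, dtype=float).ravel()) for i, g in enumerate(groups)]
    gs = [g for _, g in named]
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df = N - k
    if ssw == 0.0:
        msw = 0.0
    else:
        msw = ssw / df
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df))
            name_i = named[i][0]
            name_j = named[j][0]
            out.append(
                {
                    "pair": (
                        name_i.value if isinstance(name_i, Stage) else name_i,
                        name_j.value if isinstance(name_j, Stage) else name_j,
                    ),
                    "mean_difference": diff,
                    "p_adjusted": min(1.0, p),
                }
            )
    return out


def pca_scores(X: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Scores of the top principal components of the correlation matrix.

    Columns are standardized internally (correlation PCA); each component's
    sign is fixed so its largest-magnitude loading is positive. Scores are
    centered and mutually orthogonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a samples x features matrix with >= 2 rows")
    if n_components > X.shape[1]:
        raise ValueError("more components requested than features")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    R = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1][:n_components]
    V = eigvecs[:, order]
    for c in range(V.shape[1]):
        lead = np.argmax(np.abs(V[:, c]))
        if V[lead, c] < 0:
            V[:, c] = -V[:, c]
    return Z @ V


@dataclass
class GeneralFeatures:
    """Per-channel moment statistics of one epoch (channels x 5)."""

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    stage: Stage = Stage.UNKNOWN
    subject_id: str = ""
    epoch_index: int = 0
    feature_names: list[str] = field(
        default_factory=lambda: list(GENERAL_FEATURE_NAMES)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("general features must be finite")
        self.stage = Stage.coerce(self.stage)


def general_features(epoch: Epoch) -> GeneralFeatures:
    """Mean, population variance, max, min, and moment skewness per channel.

    Skewness is ``m3 / m2^{3/2}`` (biased moment definition); a zero-variance
    channel gets skewness 0 with a warning.
    """
    if epoch.n_samples < 3:
        raise ValueError("need at least 3 samples per channel")
    data = epoch.data
    mean = data.mean(axis=1)
    centered = data - mean[:, None]
    m2 = (centered**2).mean(axis=1)
    m3 = (centered**3).mean(axis=1)
    denom = np.where(m2 > 0, np.power(np.where(m2 > 0, m2, 1.0), 1.5), 1.0)
    skew = np.where(m2 > 0, m3 / denom, 0.0)
    if (m2 == 0).any():
        warnings.warn(
            "zero-variance channel(s): skewness reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.column_stack([mean, m2, data.max(axis=1), data.min(axis=1), skew])
    return GeneralFeatures(
        values,
        channel_names=list(epoch.channel_names),
        stage=epoch.stage,
        subject_id=epoch.subject_id,
        epoch_index=epoch.index,
    )


@dataclass
class StageSeparationReport:
    """ANOVA/Tukey table (one row per measure) plus 2-component PCA scores."""

    table: pd.DataFrame
    scores: np.ndarray
    score_labels: np.ndarray  # stage name per score row

    def table_to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def scores_to_csv(self, path) -> None:
        df = pd.DataFrame(self.scores, columns=["PC1", "PC2"])
        df["stage"] = self.score_labels
        df.to_csv(path, index=False)


def stage_separation_report(
    feature_matrices: list[FeatureMatrix],
) -> StageSeparationReport:
    """Per-measure stage comparison mirroring the package's reporting table.

    For each of the five measures, values are pooled over epochs and channels
    per stage, then compared by one-way ANOVA; Tukey pairwise differences and
    adjusted p-values are reported for normal-acute and normal-chronic. PCA
    scores are computed on the pooled (epoch x channel) x 5 matrix.
    """
    present = {fm.stage for fm in feature_matrices}
    for st in _STAGE_ORDER:
        if st not in present:
            raise ValueError(f"stage {st.value!r} missing from feature matrices")

    rows = []
    for m_idx, m_name in enumerate(MEASURE_NAMES):
        groups = StageGroups(
            {
                st: np.concatenate(
                    [
                        fm.values[:, m_idx]
                        for fm in feature_matrices
                        if fm.stage is st
                    ]
                )
                for st in _STAGE_ORDER
            }
        )
        F, p = one_way_anova(groups)
        pairs = {t["pair"]: t for t in tukey_hsd(groups)}
        na = pairs[("normal", "acute")]
        nc = pairs[("normal", "chronic")]
        rows.append(
            {
                "measure": m_name,
                "diff_normal_acute": na["mean_difference"],
                "p_normal_acute": na["p_adjusted"],
                "diff_normal_chronic": nc["mean_difference"],
                "p_normal_chronic": nc["p_adjusted"],
                "F": F,
                "p": p,
            }
        )

    X = np.concatenate([fm.values for fm in feature_matrices], axis=0)
    labels = np.concatenate(
        [[fm.stage.value] * fm.n_channels for fm in feature_matrices]
    )
    scores = pca_scores(X, n_components=2)
    return StageSeparationReport(
        table=pd.DataFrame(rows), scores=scores, score_labels=labels
    )
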