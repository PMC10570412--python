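"""Complete-graph samples and dataset splitting.

Every epoch becomes one :class:`GraphSample`: a complete graph on the eight
electrode channels (all inter-node edges 1, no self-loops) whose node features
are the epoch's 8x5 complexity matrix, labeled by stage. The uniform topology
is deliberate — stage information enters only through the node features, so
the classifier cannot latch onto connectivity differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .complexity import FeatureMatrix, MEASURE_NAMES
from .signal_io import Stage

__all__ = [
    "GraphSample",
    "DatasetSplit",
    "FeatureScaler",
    "complete_adjacency",
    "build_graph",
    "split_dataset",
    "standardize_features",
]

N_NODES = 8
N_FEATURES = len(MEASURE_NAMES)


def complete_adjacency(n_nodes: int = N_NODES) -> np.ndarray:
    """Adjacency of the complete graph K_n: off-diagonal ones, zero diagonal."""
    adj = np.ones((n_nodes, n_nodes)) - np.eye(n_nodes)
    return adj


@dataclass
class GraphSample:
    """One labeled graph: K8 adjacency + 8x5 node features."""

    adjacency: np.ndarray
    node_features: np.ndarray
    label: int
    subject_id: str = ""
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.node_features = np.asarray(self.node_features, dtype=float)
        if self.adjacency.shape != (N_NODES, N_NODES):
            raise ValueError(f"adjacency must be {N_NODES}x{N_NODES}")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.node_features.shape != (N_NODES, N_FEATURES):
            raise ValueError(f"node features must be {N_NODES}x{N_FEATURES}")
        if not np.isfinite(self.node_features).all():
            raise ValueError("node features must be finite")
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0/1/2, got {self.label}")

    @property
    def stage(self) -> Stage:
        return Stage.from_index(self.label)


def build_graph(fm: FeatureMatrix) -> GraphSample:
    """Wrap an 8x5 feature matrix as a complete-graph sample."""
    if fm.values.shape != (N_NODES, N_FEATURES):
        raise ValueError(
            f"expected an {N_NODES}x{N_FEATURES} feature matrix, got {fm.values.shape}"
        )
    if fm.stage is Stage.UNKNOWN:
        raise ValueError("cannot label a graph from an unknown stage")
    return GraphSample(
        adjacency=complete_adjacency(),
        node_features=fm.values.copy(),
        label=fm.stage.class_index,
        subject_id=fm.subject_id,
        epoch_index=fm.epoch_index,
    )


@dataclass
class DatasetSplit:
    """Train / validation / test partition of graph samples."""

    train: list[GraphSample]
    validation: list[GraphSample]
    test: list[GraphSample]
    ratios: tuple[float, float, float] = (0.5, 0.2, 0.3)
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def n_samples(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def _partition_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(round(n * ratios[0]))
    n_val = int(round(n * ratios[1]))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def split_dataset(
    samples: list[GraphSample],
    ratios: tuple[float, float, float] = (0.5, 0.2, 0.3),
    seed: int = 0,
    stratify: bool = True,
) -> DatasetSplit:
    """Deterministic shuffled split; stratified by class (default).

    With stratification each class is partitioned separately, so per-class
    proportions in each set match the ratios to within rounding.
    """
    if not samples:
        raise ValueError("cannot split an empty sample list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    groups: dict[int, list[GraphSample]]
    if stratify:
        groups = {}
        for s in samples:
            groups.setdefault(s.label, []).append(s)
        if any(len(g) < 1 for g in groups.values()):
            raise ValueError("every class needs at least one sample to stratify")
    else:
        groups = {0: list(samples)}

    train: list[GraphSample] = []
    val: list[GraphSample] = []
    test: list[GraphSample] = []
    for label in sorted(groups):
        grp = groups[label]
        order = rng.permutation(len(grp))
        n_tr, n_va, _ = _partition_sizes(len(grp), ratios)
        for pos, idx in enumerate(order):
            if pos < n_tr:
                train.append(grp[idx])
            elif pos < n_tr + n_va:
                val.append(grp[idx])
            else:
                test.append(grp[idx])
    return DatasetSplit(train, val, test, ratios=tuple(ratios), seed=seed)


@dataclass
class FeatureScaler:
    """Per-feature standardization parameters fitted on the training set."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def standardize_features(split: DatasetSplit) -> tuple[DatasetSplit, FeatureScaler]:
    """Standardize node features column-wise using training-set statistics only.

    Means/SDs are computed over all training nodes (samples x channels) per
    measure and applied unchanged to validation and test — no leakage. A
    zero-variance feature keeps its values (SD replaced by 1, with a warning).
    """
    if not split.train:
        raise ValueError("train set is empty")
    stacked = np.concatenate([s.node_features for s in split.train], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance feature column(s) {np.where(zero)[0].tolist()}; "
            "SD replaced by 1",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    scaler = FeatureScaler(mean=mean, sd=sd)

    def apply(samples: list[GraphSample]) -> list[GraphSample]:
        return [
            replace(s, node_features=scaler.transform(s.node_features))
            for s in samples
        ]

    new = DatasetSplit(
        apply(split.train),
        apply(split.validation),
        apply(split.test),
        ratios=split.ratios,
        seed=split.seed,
    )
    return new, scaler


def export_manifest(split: DatasetSplit, path) -> None:
    """Write a manifest CSV: sample id, subject, stage, assigned split."""
    rows = []
    for name, part in zip(("train", "validation", "test"), split):
        for s in part:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "epoch_index": s.epoch_index,
                    "stage": s.stage.value,
                    "split": name,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
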