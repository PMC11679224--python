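"""Training-fold class balancing.

SMOTE (k-nearest-neighbor interpolation between minority samples) and
plain random oversampling.  Both are applied strictly after the
train/test split; synthetic samples carry tagged subject ids so that a
pipeline-level guard can verify none ever reaches a test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["LabeledDataset", "smote", "random_oversample", "SYNTHETIC_PREFIX", "get_sampler"]

SYNTHETIC_PREFIX = "synthetic:"
DEFAULT_K = 5


@dataclass
class LabeledDataset:
    vectors: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) of {0, 1}
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2D")
        if len(self.labels) != self.vectors.shape[0] or len(self.subject_ids) != len(self.labels):
            raise ValueError("vectors, labels and subject_ids must align")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))


def _split_minority(data: LabeledDataset) -> tuple[int, np.ndarray, int]:
    n0, n1 = data.class_counts
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    minority_label = 0 if n0 < n1 else 1
    idx = np.flatnonzero(data.labels == minority_label)
    deficit = abs(n0 - n1)
    return minority_label, idx, deficit


def _append(data: LabeledDataset, rows: np.ndarray, label: int, tag: str) -> LabeledDataset:
    ids = data.subject_ids + [
        f"{SYNTHETIC_PREFIX}{tag}-{i + 1:04d}" for i in range(rows.shape[0])
    ]
    return LabeledDataset(
        vectors=np.vstack([data.vectors, rows]),
        labels=np.concatenate([data.labels, np.full(rows.shape[0], label, dtype=int)]),
        subject_ids=ids,
    )


def smote(data: LabeledDataset, k_neighbors: int = DEFAULT_K, seed: int = 0) -> LabeledDataset:
    """Balance the dataset by synthetic minority interpolation.

    Each synthetic sample is ``x + u * (x_nn - x)`` for a uniformly drawn
    minority sample x, one of its ``k_neighbors`` nearest minority
    neighbors (Euclidean), and a single gap u ~ Uniform(0, 1) shared
    across coordinates.  Originals are returned unchanged, in place.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    minority_label, idx, deficit = _split_minority(data)
    if deficit == 0:
        return data
    rng = np.random.default_rng(seed)
    X_min = data.vectors[idx]
    if idx.size == 1:
        warnings.warn(
            "minority class has a single sample; falling back to duplication",
            RuntimeWarning,
            stacklevel=2,
        )
        rows = np.repeat(X_min, deficit, axis=0)
        return _append(data, rows, minority_label, "smote")
    k = k_neighbors
    if k >= idx.size:
        k = idx.size - 1
        warnings.warn(
            f"k_neighbors clipped to {k} (minority class has {idx.size} samples)",
            RuntimeWarning,
            stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, idx.size, size=deficit)
    pick = rng.integers(0, k, size=deficit)
    gaps = rng.uniform(0.0, 1.0, size=deficit)
    x = X_min[base]
    x_nn = X_min[neighbors[base, pick]]
    rows = x + gaps[:, None] * (x_nn - x)
    return _append(data, rows, minority_label, "smote")


def random_oversample(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Balance by duplicating uniformly drawn minority rows."""
    minority_label, idx, deficit = _split_minority(data)
    if deficit == 0:
        return data
    rng = np.random.default_rng(seed)
    rows = data.vectors[rng.choice(idx, size=deficit, replace=True)]
    return _append(data, rows, minority_label, "random")


def get_sampler(name: str):
    """Resolve a sampler by name: 'smote', 'random' or 'none'."""
    if name == "smote":
        return smote
    if name == "random":
        return lambda data, k_neighbors=DEFAULT_K, seed=0: random_oversample(data, seed)
    if name == "none":
        return lambda data, k_neighbors=DEFAULT_K, seed=0: data
    raise ValueError(f"unknown sampler {name!r}")
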