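"""Spatio-temporal feature aggregation (STFA).

Multi-scale 2D convolutional aggregation of each subject's time-course
matrix (T' x N) and spatial-similarity matrix (R x N) into one fused
feature vector.  Each branch is convolved with banks of odd-sized
kernels (default 3,5,7,9,11), rectified, and 6x6 max-pooled (stride 6,
partial edge windows kept), then all pooled maps are flattened and
concatenated: time branch first, then spatial branch, scales in the
configured order.

The filter banks are fixed seeded random projections: the fusion stage
is deterministic and training-free, with all learnable capacity placed
in the downstream classifier.  Filters for each (branch, kernel) pair
are drawn from an independent seeded stream, so adding a scale never
changes the features of existing scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ica import SubjectFeatureSet

__all__ = ["ConvBankParams", "FusedFeature", "conv_branch", "fuse_features", "fuse_subject"]

DEFAULT_KERNEL_SIZES = (3, 5, 7, 9, 11)
DEFAULT_N_FILTERS = 8
DEFAULT_POOL = 6
BRANCHES = ("time", "spatial")


@dataclass
class ConvBankParams:
    """Fixed random filter banks for both branches."""

    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    n_filters: int = DEFAULT_N_FILTERS
    pool_size: int = DEFAULT_POOL
    seed: int = 0
    weights: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        if not self.kernel_sizes:
            raise ValueError("need at least one kernel size")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not self.weights:
            self.weights = {
                branch: {k: self._draw(branch_idx, k) for k in self.kernel_sizes}
                for branch_idx, branch in enumerate(BRANCHES)
            }

    def _draw(self, branch_idx: int, k: int) -> np.ndarray:
        # independent stream per (branch, kernel): scale subsets reuse weights
        rng = np.random.default_rng([self.seed, branch_idx, k])
        return rng.standard_normal((self.n_filters, k, k)) / k


@dataclass
class FusedFeature:
    subject_id: str
    vector: np.ndarray
    label: int
    layout: list[dict]  # per-(branch, kernel) slice records


def _correlate2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded 2D cross-correlation of ``x`` with one kernel ``w``."""
    k = w.shape[0]
    p = k // 2
    xp = np.pad(x, p)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k))
    return np.einsum("ijkl,kl->ij", win, w)


def _max_pool(x: np.ndarray, p: int) -> np.ndarray:
    """p x p max pooling, stride p, ceil mode (partial edge windows kept)."""
    H, W = x.shape
    Hp, Wp = -(-H // p), -(-W // p)
    padded = np.full((Hp * p, Wp * p), -np.inf)
    padded[:H, :W] = x
    return padded.reshape(Hp, p, Wp, p).max(axis=(1, 3))


def conv_branch(matrix: np.ndarray, params: ConvBankParams, branch: str = "time") -> dict[int, np.ndarray]:
    """Conv -> ReLU -> max-pool for every scale of one branch.

    Returns ``{kernel_size: (n_filters, ceil(H/p), ceil(W/p)) array}``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("input must be a non-empty 2D matrix")
    if branch not in params.weights:
        raise ValueError(f"unknown branch {branch!r}")
    out: dict[int, np.ndarray] = {}
    for k in params.kernel_sizes:
        bank = params.weights[branch][k]
        p = k // 2
        win = np.lib.stride_tricks.sliding_window_view(np.pad(matrix, p), (k, k))
        conv = np.maximum(np.einsum("ijkl,fkl->fij", win, bank), 0.0)
        out[k] = np.stack([_max_pool(conv[f], params.pool_size) for f in range(params.n_filters)])
    return out


def fuse_features(
    timecourses: np.ndarray,
    spatial_features: np.ndarray,
    params: ConvBankParams,
    subject_id: str = "",
    label: int = 0,
) -> FusedFeature:
    """Concatenate the pooled multi-scale maps of both branches.

    Order: time branch over all scales (configured order), then spatial
    branch over all scales; each block flattened in C order.  The layout
    records the slice boundaries and pooled shapes per block.
    """
    pieces: list[np.ndarray] = []
    layout: list[dict] = []
    start = 0
    for branch, matrix in (("time", timecourses), ("spatial", spatial_features)):
        pooled = conv_branch(matrix, params, branch)
        for k in params.kernel_sizes:
            flat = pooled[k].ravel()
            layout.append(
                {
                    "branch": branch,
                    "kernel": int(k),
                    "start": int(start),
                    "stop": int(start + flat.size),
                    "shape": [int(d) for d in pooled[k].shape],
                }
            )
            pieces.append(flat)
            start += flat.size
    return FusedFeature(
        subject_id=subject_id,
        vector=np.concatenate(pieces),
        label=int(label),
        layout=layout,
    )


def fuse_subject(fs: SubjectFeatureSet, params: ConvBankParams) -> FusedFeature:
    return fuse_features(
        fs.timecourses, fs.spatial_features, params,
        subject_id=fs.subject_id, label=fs.label,
    )
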