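"""Group ICA feature extraction.

Stage 1 of the pipeline: temporal-concatenation group ICA over the
cohort, per-subject back-reconstruction of mixing time courses, and
multiple linear regression of spatial maps against an RSN template.

The group decomposition follows the standard two-stage scheme: a
subject-level PCA reduction, concatenation across subjects, a group-level
PCA whitening to the requested model order, and a FastICA unmixing of the
whitened matrix.  Component stability across restarts is handled by a
simplified restart-matching scheme (absolute-correlation Hungarian
matching, centroid components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synth import RSNAtlas, SubjectScan

__all__ = [
    "ICADecomposition",
    "SpatialSimilarity",
    "SubjectFeatureSet",
    "GroupReduction",
    "discard_initial_volumes",
    "group_reduce",
    "fastica_decompose",
    "stability_select",
    "subject_timecourses",
    "rsn_regression",
    "extract_features",
]

DEFAULT_N_COMPONENTS = 17
DEFAULT_DISCARD = 5
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 200
#: subject-level PCA keeps this multiple of the model order (capped at T')
SUBJECT_PCA_FACTOR = 1.5


@dataclass
class GroupReduction:
    """Whitened group matrix plus bookkeeping for reporting."""

    whitened: np.ndarray  # (n_components, V)
    singular_values: np.ndarray
    explained_variance_ratio: float
    n_subjects: int


@dataclass
class ICADecomposition:
    """Group sources with unmixing and per-subject time courses."""

    sources: np.ndarray  # Y, (N, V), unit-variance rows
    unmixing: np.ndarray  # W, (N, N) acting on the whitened matrix
    group_mixing: np.ndarray  # (N, N), pseudo-inverse of W
    n_components: int
    converged: bool = True
    subject_timecourses: dict[str, np.ndarray] = field(default_factory=dict)
    stability: np.ndarray | None = None  # per-component mean |corr| to centroid


@dataclass
class SpatialSimilarity:
    """Regression of component maps on the RSN template (Q = Y @ beta)."""

    Q: np.ndarray  # (N, R) regression coefficients per component
    beta_basis: np.ndarray  # (V, R) template design matrix

    @property
    def spatial_features(self) -> np.ndarray:
        """R x N view consumed by the convolutional fusion stage."""
        return self.Q.T


@dataclass
class SubjectFeatureSet:
    subject_id: str
    timecourses: np.ndarray  # (T', N)
    spatial_features: np.ndarray  # (R, N)
    label: int


def discard_initial_volumes(scan: SubjectScan, k: int = DEFAULT_DISCARD) -> SubjectScan:
    """Drop the first ``k`` volumes (scanner equilibration period)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= scan.n_timepoints:
        raise ValueError(
            f"cannot discard {k} of {scan.n_timepoints} timepoints"
        )
    return SubjectScan(
        subject_id=scan.subject_id, data=scan.data[k:].copy(), label=scan.label
    )


def _center_rows(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def group_reduce(scans: list[SubjectScan], n_components: int) -> tuple[np.ndarray, GroupReduction]:
    """Two-stage PCA reduction of the temporally concatenated cohort.

    Each subject's row-centered data is reduced to the top
    ``ceil(1.5 * n_components)`` temporal principal components (capped at
    T'), subjects are stacked, and a group PCA whitens down to
    ``n_components`` rows with exact identity covariance across voxels.
    """
    if not scans:
        raise ValueError("need at least one scan")
    T = scans[0].n_timepoints
    V = scans[0].n_voxels
    for s in scans:
        if s.n_timepoints != T or s.n_voxels != V:
            raise ValueError("all scans must share the same T and V")
    if n_components < 1 or n_components > T:
        raise ValueError("n_components must be in [1, T']")

    n1 = min(T, int(np.ceil(SUBJECT_PCA_FACTOR * n_components)))
    blocks = []
    for s in scans:
        Xc = _center_rows(s.data)
        U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        blocks.append(sv[:n1, None] * Vt[:n1])
    concat = _center_rows(np.vstack(blocks))
    U, sv, Vt = np.linalg.svd(concat, full_matrices=False)
    whitened = np.sqrt(V - 1) * Vt[:n_components]
    total = float(np.sum(sv**2))
    evr = float(np.sum(sv[:n_components] ** 2) / total) if total > 0 else 1.0
    info = GroupReduction(
        whitened=whitened,
        singular_values=sv[:n_components].copy(),
        explained_variance_ratio=evr,
        n_subjects=len(scans),
    )
    return whitened, info


def _fix_signs(Y: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its maximum-magnitude voxel is positive."""
    flips = np.ones(Y.shape[0])
    for i in range(Y.shape[0]):
        j = int(np.argmax(np.abs(Y[i])))
        if Y[i, j] < 0:
            flips[i] = -1.0
    return Y * flips[:, None], W * flips[:, None]


def fastica_decompose(
    whitened: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ICADecomposition:
    """FastICA unmixing of a pre-whitened group matrix (Y = W @ whitened)."""
    whitened = np.asarray(whitened, dtype=float)
    if not np.all(np.isfinite(whitened)):
        raise ValueError("whitened matrix contains non-finite values")
    if n_components is None:
        n_components = whitened.shape[0]
    if n_components != whitened.shape[0]:
        raise ValueError("whitened matrix must already have n_components rows")

    ica = FastICA(
        n_components=n_components,
        whiten=False,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica.fit(whitened.T)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
    if not converged:
        warnings.warn(
            "FastICA did not converge within max_iter; returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    W = np.asarray(ica.components_, dtype=float)
    Y = W @ whitened
    # exact unit-variance rows (W is orthonormal up to numerical error)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    scale = np.where(sd > 0, sd, 1.0)
    Y = Y / scale
    W = W / scale
    Y, W = _fix_signs(Y, W)
    return ICADecomposition(
        sources=Y,
        unmixing=W,
        group_mixing=np.linalg.pinv(W),
        n_components=n_components,
        converged=converged,
    )


def stability_select(
    whitened: np.ndarray,
    n_components: int | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ICADecomposition:
    """Restart-matched stable decomposition.

    Runs FastICA ``n_restarts`` times (first restart with ``seed``
    itself), matches every restart's components to the first run by
    absolute correlation (Hungarian assignment), aligns signs, and
    returns the centroid components renormalized to unit variance.
    ``stability`` records each component's mean |correlation| with its
    cluster centroid.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if n_restarts == 1:
        return fastica_decompose(whitened, n_components, seed, tol, max_iter)

    rng = np.random.default_rng(seed)
    seeds = [seed] + [int(s) for s in rng.integers(0, 2**31 - 1, n_restarts - 1)]
    runs = [
        fastica_decompose(whitened, n_components, s, tol, max_iter) for s in seeds
    ]
    ref = runs[0].sources
    N = ref.shape[0]
    aligned = [ref]
    for run in runs[1:]:
        C = np.corrcoef(ref, run.sources)[:N, N:]
        row, col = linear_sum_assignment(-np.abs(C))
        signs = np.sign(C[row, col])
        signs[signs == 0] = 1.0
        aligned.append(run.sources[col] * signs[:, None])
    stack = np.stack(aligned)  # (n_restarts, N, V)
    centroid = stack.mean(axis=0)
    sd = centroid.std(axis=1, ddof=1, keepdims=True)
    centroid = centroid / np.where(sd > 0, sd, 1.0)
    compact = np.empty(N)
    for i in range(N):
        cors = [
            abs(np.corrcoef(centroid[i], stack[r, i])[0, 1])
            for r in range(n_restarts)
        ]
        compact[i] = float(np.mean(cors))
    W = np.linalg.lstsq(whitened.T, centroid.T, rcond=None)[0].T
    Y = W @ whitened
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    scale = np.where(sd > 0, sd, 1.0)
    Y, W = _fix_signs(Y / scale, W / scale)
    return ICADecomposition(
        sources=Y,
        unmixing=W,
        group_mixing=np.linalg.pinv(W),
        n_components=Y.shape[0],
        converged=all(r.converged for r in runs),
        stability=compact,
    )


def subject_timecourses(scan: SubjectScan, Y: np.ndarray) -> np.ndarray:
    """Least-squares back-reconstruction of a subject's mixing matrix.

    Solves min_A ||X - A @ Y||^2 for the T' x N time-course matrix.
    """
    Y = np.asarray(Y, dtype=float)
    if scan.n_voxels != Y.shape[1]:
        raise ValueError("scan and sources must share the voxel dimension")
    A, _, rank, _ = np.linalg.lstsq(Y.T, scan.data.T, rcond=None)
    if rank < Y.shape[0]:
        warnings.warn(
            "rank-deficient source matrix; returning pseudo-inverse solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return A.T


def rsn_regression(Y: np.ndarray, atlas: RSNAtlas) -> SpatialSimilarity:
    """Regress each component map onto the RSN template (Q = Y @ beta).

    For each component row y_n, fits y_n ~ atlas @ b_n by ordinary least
    squares; Q stacks the coefficient vectors b_n as rows (N x R).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be an N x V matrix")
    if Y.shape[1] != atlas.n_voxels:
        raise ValueError("component maps and atlas must share V")
    B, _, _, _ = np.linalg.lstsq(atlas.maps, Y.T, rcond=None)  # (R, N)
    return SpatialSimilarity(Q=B.T, beta_basis=atlas.maps)


def extract_features(
    scans: list[SubjectScan],
    atlas: RSNAtlas,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_restarts: int = 10,
    seed: int = 0,
    discard: int = DEFAULT_DISCARD,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[list[SubjectFeatureSet], ICADecomposition, SpatialSimilarity]:
    """Full stage-1 pipeline: discard -> group ICA -> per-subject features.

    Per-subject spatial features are obtained GIFT-style: the subject's
    spatial maps are back-reconstructed by least squares from its own
    data and time courses, then regressed against the atlas, giving an
    R x N matrix per subject (the group-level similarity is returned
    alongside).
    """
    trimmed = [discard_initial_volumes(s, discard) for s in scans]
    whitened, _ = group_reduce(trimmed, n_components)
    decomp = stability_select(
        whitened, n_components, n_restarts=n_restarts, seed=seed,
        tol=tol, max_iter=max_iter,
    )
    group_sim = rsn_regression(decomp.sources, atlas)
    feature_sets: list[SubjectFeatureSet] = []
    for scan in trimmed:
        A = subject_timecourses(scan, decomp.sources)
        decomp.subject_timecourses[scan.subject_id] = A
        # subject-specific spatial maps: min_S ||X - A S||^2
        S_subj, _, _, _ = np.linalg.lstsq(A, scan.data, rcond=None)
        sim = rsn_regression(S_subj, atlas)
        feature_sets.append(
            SubjectFeatureSet(
                subject_id=scan.subject_id,
                timecourses=A,
                spatial_features=sim.spatial_features,
                label=scan.label,
            )
        )
    return feature_sets, decomp, group_sim
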