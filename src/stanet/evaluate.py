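"""Subject-level cross-validation and performance metrics.

Folds are assigned at the subject level (stratified by default so every
test fold contains both classes), oversampling is applied to training
folds only, and the reported ACC/SEN/PPV/F1/Recall/AUC are per-fold
means.  AUC uses the Mann-Whitney rank formulation with half credit for
ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from . import afgru
from .oversample import SYNTHETIC_PREFIX, LabeledDataset, get_sampler
from .stfa import FusedFeature

__all__ = [
    "FoldAssignment",
    "ConfusionCounts",
    "MetricsReport",
    "kfold_split",
    "confusion",
    "metrics",
    "auc_score",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    fold_of_subject: dict[str, int]  # subject_id -> fold index in 0..k-1
    k: int

    def test_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_subject.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_subject.items() if f != fold]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    ACC: float
    SEN: float
    PPV: float
    F1: float
    Recall: float
    AUC: float
    per_fold: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ACC": self.ACC, "SEN": self.SEN, "PPV": self.PPV,
            "F1": self.F1, "Recall": self.Recall, "AUC": self.AUC,
            "per_fold": self.per_fold,
        }


def kfold_split(
    subject_ids: list[str],
    k: int,
    seed: int,
    labels: np.ndarray | None = None,
    stratify: bool = True,
) -> FoldAssignment:
    """Random subject-level k-fold partition with fold sizes differing <= 1.

    With ``stratify`` (and labels given), subjects are shuffled within
    class and dealt to folds in one continuous stream, which preserves
    the class ratio per fold while keeping overall fold sizes balanced.
    """
    n = len(subject_ids)
    if k < 1 or k > n:
        raise ValueError("k must be in [1, n_subjects]")
    if len(set(subject_ids)) != n:
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    if stratify and labels is not None:
        labels = np.asarray(labels)
        order: list[int] = []
        for cls in sorted(set(labels.tolist()), reverse=True):
            idx = np.flatnonzero(labels == cls)
            order.extend(rng.permutation(idx).tolist())
    else:
        order = rng.permutation(n).tolist()
    fold_of = {subject_ids[j]: i % k for i, j in enumerate(order)}
    return FoldAssignment(fold_of_subject=fold_of, k=k)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """2x2 confusion table with class 1 (depressed) as positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (set(np.unique(y_true)) | set(np.unique(y_pred))) <= {0, 1}:
        raise ValueError("entries must be binary")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with 0.5 credit per tied pair."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class; reporting 0.5",
                      RuntimeWarning, stacklevel=2)
        return 0.5
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> MetricsReport:
    """ACC, SEN, PPV, F1, Recall (= SEN) and AUC from one test fold."""
    total = counts.total
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.TP + counts.TN) / total
    if counts.TP + counts.FN == 0:
        warnings.warn("no positive samples; SEN reported as 0", RuntimeWarning, stacklevel=2)
        sen = 0.0
    else:
        sen = counts.TP / (counts.TP + counts.FN)
    if counts.TP + counts.FP == 0:
        warnings.warn("no positive predictions; PPV reported as 0", RuntimeWarning, stacklevel=2)
        ppv = 0.0
    else:
        ppv = counts.TP / (counts.TP + counts.FP)
    f1 = 0.0 if sen + ppv == 0 else 2.0 * sen * ppv / (sen + ppv)
    auc = auc_score(y_true, scores) if scores is not None and y_true is not None else float("nan")
    return MetricsReport(ACC=acc, SEN=sen, PPV=ppv, F1=f1, Recall=sen, AUC=auc)


def _mean_report(fold_reports: list[MetricsReport]) -> MetricsReport:
    per_fold = [
        {"ACC": r.ACC, "SEN": r.SEN, "PPV": r.PPV, "F1": r.F1,
         "Recall": r.Recall, "AUC": r.AUC}
        for r in fold_reports
    ]
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in per_fold[0]}
    return MetricsReport(per_fold=per_fold, **mean)


def cross_validate(
    fused: list[FusedFeature],
    k: int = 10,
    sampler: str = "smote",
    smote_k: int = 5,
    seed: int = 0,
    classifier: str = "afgru",
    config: afgru.AFGRUConfig | None = None,
    stratify: bool = True,
) -> MetricsReport:
    """Subject-level k-fold cross-validation on fused feature vectors.

    Each fold: the training subjects are balanced by the chosen sampler
    (strictly after the split; a guard asserts no synthetic id reaches a
    test fold), the classifier is trained, and the held-out subjects are
    scored.  Metrics are averaged over folds.

    ``classifier`` is ``"afgru"`` or ``"logistic"`` (an L2 logistic
    regression on the standardized fused vectors, used as a linear
    reference model).
    """
    ids = [f.subject_id for f in fused]
    labels = np.array([f.label for f in fused], dtype=int)
    vectors = np.stack([f.vector for f in fused])
    layout = fused[0].layout
    folds = kfold_split(ids, k, seed, labels=labels, stratify=stratify)
    sample = get_sampler(sampler)
    rng = np.random.default_rng(seed)
    reports: list[MetricsReport] = []
    for fold in range(k):
        test_mask = np.array([folds.fold_of_subject[s] == fold for s in ids])
        train_ids = [s for s, m in zip(ids, test_mask) if not m]
        test_ids = [s for s, m in zip(ids, test_mask) if m]
        if set(train_ids) & set(test_ids):
            raise AssertionError("subject appears in both train and test folds")
        train = LabeledDataset(
            vectors=vectors[~test_mask],
            labels=labels[~test_mask],
            subject_ids=train_ids,
        )
        fold_seed = int(rng.integers(0, 2**31 - 1))
        balanced = sample(train, k_neighbors=smote_k, seed=fold_seed)
        if any(s.startswith(SYNTHETIC_PREFIX) for s in test_ids):
            raise AssertionError("synthetic sample leaked into a test fold")
        X_test, y_test = vectors[test_mask], labels[test_mask]
        if classifier == "afgru":
            cfg = config or afgru.AFGRUConfig()
            cfg = afgru.AFGRUConfig(
                hidden=cfg.hidden, layers=cfg.layers, attn_dim=cfg.attn_dim,
                lr=cfg.lr, rounds=cfg.rounds, epochs=cfg.epochs,
                val_fraction=cfg.val_fraction, seed=fold_seed,
            )
            model = afgru.train(cfg, balanced.vectors, balanced.labels, layout)
            scores_, preds = afgru.predict(model, X_test)
        elif classifier == "logistic":
            scaler = StandardScaler().fit(balanced.vectors)
            clf = LogisticRegression(max_iter=1000, random_state=fold_seed)
            clf.fit(scaler.transform(balanced.vectors), balanced.labels)
            scores_ = clf.predict_proba(scaler.transform(X_test))[:, 1]
            preds = (scores_ >= 0.5).astype(int)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        reports.append(metrics(confusion(y_test, preds), scores_, y_test))
    return _mean_report(reports)
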