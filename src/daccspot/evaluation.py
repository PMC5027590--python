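"""Cross-validation protocols and binary classification metrics.

Two protocols are provided: the jackknife (leave-one-out), in which every
sample serves once as the single test case while the remaining samples are
used for training, and stratified k-fold with a seeded shuffle.  In both,
the preprocessing that depends on the training distribution (the PCA
projection) and the SVM are refit on every training split, so no information
from a held-out sample leaks into the model evaluated on it.  Sequence
encoding is purely sequence-local and is therefore computed once up front.

Metrics: sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/total, and Matthews correlation coefficient

    Mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined as 0 when any factor of the denominator vanishes.  Hotspots are the
positive class throughout.

Implementation note: with more features than samples, leave-one-out PCA is
computed from the n x n Gram matrix of the data — the training-fold centered
Gram is an O(n^2) update of the full-data Gram, and PCA scores for both
training rows and the held-out row come from its eigendecomposition.  This
is algebraically identical to refitting PCA on the training rows in feature
space (same eigenvalues, same scores up to component sign, which the RBF
kernel is oblivious to); a test asserts agreement with the naive refit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    SOLVER_TOL,
    SvmConfig,
    predict,
    train,
)
from .encoding import parse_feature_name
from .errors import ProtocolError
from .pca import fit_pca, select_l

from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos, neg = POSITIVE_LABEL, NEGATIVE_LABEL
        return ConfusionCounts(
            tp=int(np.sum((y_true == pos) & (y_pred == pos))),
            fp=int(np.sum((y_true == neg) & (y_pred == pos))),
            tn=int(np.sum((y_true == neg) & (y_pred == neg))),
            fn=int(np.sum((y_true == pos) & (y_pred == neg))),
        )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Se, Sp, Acc, Mcc) from confusion counts; Mcc = 0 on a zero factor."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return se, sp, acc, mcc


@dataclass(frozen=True)
class EvaluationResult:
    protocol: dict
    counts: ConfusionCounts
    se: float
    sp: float
    acc: float
    mcc: float
    ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    decision: np.ndarray

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "counts": {
                "TP": self.counts.tp,
                "FP": self.counts.fp,
                "TN": self.counts.tn,
                "FN": self.counts.fn,
            },
            "metrics": {"Se": self.se, "Sp": self.sp, "Acc": self.acc, "Mcc": self.mcc},
        }

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "true_label": ["hot" if t == POSITIVE_LABEL else "cold" for t in self.y_true],
                "predicted_label": [
                    "hot" if p == POSITIVE_LABEL else "cold" for p in self.y_pred
                ],
                "decision_value": self.decision,
            }
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Per-fold modeling pipeline: optional PCA reduction, then RBF-SVM."""

    reduce: bool = True
    w: float = 0.99
    svm: SvmConfig = field(default_factory=SvmConfig)


def _result(protocol, ids, y_true, y_pred, decision) -> EvaluationResult:
    counts = ConfusionCounts.from_labels(y_true, y_pred)
    se, sp, acc, mcc = metrics(counts)
    return EvaluationResult(
        protocol=protocol,
        counts=counts,
        se=se,
        sp=sp,
        acc=acc,
        mcc=mcc,
        ids=tuple(ids),
        y_true=np.asarray(y_true),
        y_pred=np.asarray(y_pred),
        decision=np.asarray(decision),
    )


def _check_dataset(X, y, ids):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ProtocolError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    for cls in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if np.sum(y == cls) < 2:
            raise ProtocolError(
                f"class {cls:+d} has fewer than 2 members; cannot cross-validate"
            )
    if ids is None:
        ids = tuple(f"seq{i}" for i in range(X.shape[0]))
    return X, y, tuple(ids)


def _assert_no_leak(train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    if np.intersect1d(train_idx, test_idx).size:
        raise AssertionError("leakage: held-out rows passed to a fitting step")


def _svc(svm: SvmConfig, precomputed: bool = False) -> SVC:
    return SVC(
        C=svm.C,
        gamma=svm.gamma,
        kernel="precomputed" if precomputed else "rbf",
        tol=SOLVER_TOL,
        cache_size=500,
        random_state=0,
    )


def _fold_fit_predict(X, y, train_idx, test_idx, pipeline: PipelineConfig):
    """Naive per-fold refit: PCA (optional) then SVM, in feature space."""
    _assert_no_leak(train_idx, test_idx)
    Xtr, Xte = X[train_idx], X[test_idx]
    if pipeline.reduce:
        pca = fit_pca(Xtr, pipeline.w)
        Xtr, Xte = pca.transform(Xtr), pca.transform(Xte)
    model = train(Xtr, y[train_idx], pipeline.svm)
    return predict(model, Xte)


def jackknife(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: PipelineConfig | None = None,
    ids: tuple[str, ...] | None = None,
    fast_pca_reuse: bool = False,
) -> EvaluationResult:
    """Leave-one-out evaluation with per-fold PCA + SVM refits.

    ``fast_pca_reuse`` fits the PCA once on the full dataset instead of per
    training fold.  That lets the held-out sample influence the projection it
    is judged in (mild information leakage) and exists only to probe how much
    that shortcut matters; a loud warning is emitted.
    """
    pipeline = pipeline or PipelineConfig()
    X, y, ids = _check_dataset(X, y, ids)
    n = X.shape[0]
    protocol: dict = {"name": "jackknife", "n": n, "pipeline": _describe(pipeline)}

    if fast_pca_reuse and pipeline.reduce:
        warnings.warn(
            "fast_pca_reuse fits PCA on the full dataset including each "
            "held-out sample; results are subject to information leakage",
            UserWarning,
            stacklevel=2,
        )
        pca = fit_pca(X, pipeline.w)
        scores = pca.transform(X)
        y_pred, decision = _loo_precomputed_kernel(scores, y, pipeline.svm)
        protocol["pca_dimension"] = pca.l_retained
        protocol["fast_pca_reuse"] = True
        return _result(protocol, ids, y, y_pred, decision)

    if not pipeline.reduce:
        y_pred, decision = _loo_precomputed_kernel(X, y, pipeline.svm)
        return _result(protocol, ids, y, y_pred, decision)

    y_pred, decision, l_values = _loo_gram_pca(X, y, pipeline)
    protocol["pca_dimension_median"] = float(np.median(l_values))
    return _result(protocol, ids, y, y_pred, decision)


def _rbf_kernel_matrix(X: np.ndarray, gamma: float) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-gamma * d2)


def _loo_precomputed_kernel(X, y, svm: SvmConfig):
    """Leave-one-out SVM on a fixed representation via one kernel matrix.

    The RBF kernel between two training rows does not depend on which fold
    they are in, so the full kernel matrix is computed once and per-fold
    training uses its submatrices.  Exactly equivalent to refitting on raw
    rows each fold.
    """
    n = X.shape[0]
    K = _rbf_kernel_matrix(np.asarray(X, dtype=float), svm.gamma)
    y_pred = np.empty(n, dtype=int)
    decision = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        _assert_no_leak(tr, np.array([i]))
        svc = _svc(svm, precomputed=True)
        svc.fit(K[np.ix_(tr, tr)], y[tr])
        d = float(svc.decision_function(K[np.ix_([i], tr)])[0])
        decision[i] = d
        y_pred[i] = POSITIVE_LABEL if d >= 0 else NEGATIVE_LABEL
    return y_pred, decision


def _loo_gram_pca(X, y, pipeline: PipelineConfig):
    """Leave-one-out with per-fold PCA refit, computed in Gram form."""
    n = X.shape[0]
    G = X @ X.T
    y_pred = np.empty(n, dtype=int)
    decision = np.empty(n)
    l_values = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        _assert_no_leak(tr, np.array([i]))
        Gt = G[np.ix_(tr, tr)]
        row_mean = Gt.mean(axis=0)
        total_mean = row_mean.mean()
        Gc = Gt - row_mean[None, :] - row_mean[:, None] + total_mean
        eigval, U = np.linalg.eigh(Gc)
        eigval = eigval[::-1]
        U = U[:, ::-1]
        np.clip(eigval, 0.0, None, out=eigval)
        rank = int(np.sum(eigval > max(eigval[0], 1.0) * 1e-12))
        total = float(np.trace(Gc))
        l = min(select_l(eigval, total, pipeline.w), rank)
        l_values[i] = l
        s = np.sqrt(eigval[:l])
        scores_tr = U[:, :l] * s
        # centered cross products of the held-out row with training rows
        c = G[i, tr] - G[i, tr].mean() - row_mean + total_mean
        score_te = (c @ U[:, :l]) / s
        model = train(scores_tr, y[tr], pipeline.svm)
        d = float(model.decision_values(score_te[None, :])[0])
        decision[i] = d
        y_pred[i] = POSITIVE_LABEL if d >= 0 else NEGATIVE_LABEL
    return y_pred, decision, l_values


def kfold(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    seed: int = 0,
    pipeline: PipelineConfig | None = None,
    ids: tuple[str, ...] | None = None,
) -> EvaluationResult:
    """Stratified k-fold with seeded shuffle and per-fold refits.

    ``k == n`` degenerates to leave-one-out (single-sample folds), matching
    the jackknife up to fold bookkeeping.
    """
    pipeline = pipeline or PipelineConfig()
    X, y, ids = _check_dataset(X, y, ids)
    n = X.shape[0]
    if k < 2:
        raise ProtocolError(f"k must be >= 2, got {k}")
    if k == n:
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        smallest = min(np.sum(y == POSITIVE_LABEL), np.sum(y == NEGATIVE_LABEL))
        if k > smallest:
            raise ProtocolError(
                f"k={k} exceeds the smaller class size {smallest}; folds would "
                "miss a class"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))

    y_pred = np.empty(n, dtype=int)
    decision = np.empty(n)
    for train_idx, test_idx in splits:
        labels, d = _fold_fit_predict(X, y, train_idx, test_idx, pipeline)
        y_pred[test_idx] = labels
        decision[test_idx] = d
    protocol = {"name": "k-fold", "k": k, "seed": seed, "n": n,
                "pipeline": _describe(pipeline)}
    return _result(protocol, ids, y, y_pred, decision)


def lag_sweep(
    X_full: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...],
    lags: list[int],
    seed: int = 0,
    folds: int = 5,
    pipeline: PipelineConfig | None = None,
) -> pd.DataFrame:
    """5-fold accuracy as a function of the maximum lag.

    ``X_full`` must be encoded at a maximum lag covering every requested lag;
    the feature subset for a smaller maximum lag is a column slice, since a
    feature's value does not depend on the encoder's maximum lag.  The same
    fold seed is used for every lag so rows are comparable.
    """
    pipeline = pipeline or PipelineConfig()
    lag_of = np.array([parse_feature_name(nm)[2] for nm in feature_names])
    max_available = int(lag_of.max())
    rows = []
    for lag in lags:
        if lag < 1 or lag > max_available:
            raise ValueError(
                f"lag {lag} outside the encoded range 1..{max_available}"
            )
        cols = np.flatnonzero(lag_of <= lag)
        result = kfold(X_full[:, cols], y, k=folds, seed=seed, pipeline=pipeline)
        rows.append({"lag": lag, "n_features": cols.size, "acc": result.acc,
                     "mcc": result.mcc})
    return pd.DataFrame(rows)


def _describe(pipeline: PipelineConfig) -> dict:
    return {
        "reduce": pipeline.reduce,
        "w": pipeline.w,
        "C": pipeline.svm.C,
        "gamma": pipeline.svm.gamma,
    }
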