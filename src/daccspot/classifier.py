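"""RBF-kernel SVM training, grid search, and discriminative feature weights.

The classifier is a C-SVC with radial basis kernel
``K(x, x') = exp(-gamma ||x - x'||^2)``.  Defaults ``C = 2**3`` and
``gamma = 2**-3`` are the operating point used throughout the package.

The discriminative weight vector ranks features by

    W_j = sum_i A_i * M_ij,

where ``A_i = alpha_i * y_i`` is the signed dual coefficient of training
sample ``i`` (zero off the support set) and ``M`` is the training feature
matrix.  This is a pseudo-linear read-out of an RBF model — it applies a
linear-kernel weight formula to a nonlinear fit — and is used for ranking
only; ranking is by ``|W_j|`` with the sign retained in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ProtocolError, ShapeError

#: libsvm stopping tolerance, fixed for reproducibility
SOLVER_TOL = 1e-4

POSITIVE_LABEL = 1  # hotspot
NEGATIVE_LABEL = -1  # coldspot


def default_grid() -> list[tuple[float, float]]:
    """log2 C in [-5, 15], log2 gamma in [-15, 3], step 2."""
    return [
        (2.0**lc, 2.0**lg)
        for lc in range(-5, 16, 2)
        for lg in range(-15, 4, 2)
    ]


@dataclass(frozen=True)
class SvmConfig:
    C: float = 8.0
    gamma: float = 0.125

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError(f"C and gamma must be positive, got {self.C}, {self.gamma}")


@dataclass
class TrainedModel:
    """A fitted SVM plus bookkeeping needed for prediction and weights."""

    svc: SVC
    config: SvmConfig
    n_training_samples: int
    # signed dual coefficients A_i over ALL training samples (zero off support)
    sample_weights: np.ndarray = field(repr=False)

    @property
    def n_features(self) -> int:
        return self.svc.n_features_in_

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ShapeError(
                f"matrix has {X.shape[1]} columns, model expects {self.n_features}"
            )
        return self.svc.decision_function(X)


@dataclass(frozen=True)
class DiscriminativeWeights:
    names: tuple[str, ...]
    weights: np.ndarray

    @property
    def ranking(self) -> np.ndarray:
        """Feature indices ordered by |W| descending (stable for ties)."""
        return np.argsort(-np.abs(self.weights), kind="stable")

    def rank_of(self, feature: str | int) -> int:
        """1-based rank of a feature in the |W| ordering."""
        idx = feature if isinstance(feature, int) else self.names.index(feature)
        return int(np.flatnonzero(self.ranking == idx)[0]) + 1

    def to_frame(self) -> pd.DataFrame:
        order = np.empty(len(self.names), dtype=int)
        order[self.ranking] = np.arange(1, len(self.names) + 1)
        return pd.DataFrame(
            {
                "feature": list(self.names),
                "weight": self.weights,
                "abs_weight": np.abs(self.weights),
                "rank": order,
            }
        )


def _as_pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    values = set(np.unique(y).tolist())
    if not values <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
        raise ValueError(f"labels must be +/-1 (hot=+1, cold=-1), got {sorted(values)}")
    if len(values) < 2:
        raise ProtocolError("training requires both classes present")
    return y.astype(int)


def train(X: np.ndarray, y: np.ndarray, config: SvmConfig | None = None) -> TrainedModel:
    """Fit a C-SVC with RBF kernel on a labeled matrix (labels +/-1)."""
    config = config or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = _as_pm1(y)
    if X.shape[0] != y.shape[0]:
        raise ShapeError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    svc = SVC(
        C=config.C,
        gamma=config.gamma,
        kernel="rbf",
        tol=SOLVER_TOL,
        cache_size=500,
        random_state=0,
    )
    svc.fit(X, y)
    A = np.zeros(X.shape[0])
    A[svc.support_] = svc.dual_coef_[0]
    return TrainedModel(
        svc=svc,
        config=config,
        n_training_samples=X.shape[0],
        sample_weights=A,
    )


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values; a decision value of exactly 0 -> hotspot."""
    decision = model.decision_values(X)
    labels = np.where(decision >= 0.0, POSITIVE_LABEL, NEGATIVE_LABEL)
    return labels, decision


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[tuple[float, float]] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[SvmConfig, pd.DataFrame]:
    """Pick (C, gamma) maximizing mean stratified-CV accuracy.

    Ties break toward smaller C, then smaller gamma (the simpler model).
    Returns the winning config and the full results table.
    """
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if folds < 2:
        raise ProtocolError(f"grid search needs >= 2 folds, got {folds}")
    X = np.asarray(X, dtype=float)
    y = _as_pm1(y)
    counts = min(np.sum(y == POSITIVE_LABEL), np.sum(y == NEGATIVE_LABEL))
    if folds > counts:
        raise ProtocolError(
            f"{folds} stratified folds impossible with a class of size {counts}"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))

    rows = []
    for C, gamma in grid:
        config = SvmConfig(C=C, gamma=gamma)
        correct = 0
        for train_idx, test_idx in splits:
            model = train(X[train_idx], y[train_idx], config)
            pred, _ = predict(model, X[test_idx])
            correct += int(np.sum(pred == y[test_idx]))
        rows.append({"C": C, "gamma": gamma, "cv_accuracy": correct / len(y)})
    table = pd.DataFrame(rows)
    best = min(
        range(len(grid)),
        key=lambda i: (-table.cv_accuracy[i], table.C[i], table.gamma[i]),
    )
    return SvmConfig(C=float(table.C[best]), gamma=float(table.gamma[best])), table


def discriminative_weights(
    model: TrainedModel,
    M: np.ndarray,
    names: tuple[str, ...] | None = None,
) -> DiscriminativeWeights:
    """Per-feature scores ``W = A @ M`` over the model's training matrix."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ShapeError(f"training matrix must be 2-D, got shape {M.shape}")
    if M.shape[0] != model.n_training_samples:
        raise ShapeError(
            f"matrix has {M.shape[0]} rows, model was trained on "
            f"{model.n_training_samples}"
        )
    W = model.sample_weights @ M
    if names is None:
        names = tuple(f"f{j}" for j in range(M.shape[1]))
    if len(names) != M.shape[1]:
        raise ShapeError("one name per feature column is required")
    return DiscriminativeWeights(names=tuple(names), weights=W)
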