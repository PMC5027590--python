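"""Principal component analysis with cumulative-variance component selection.

The number of retained components is the smallest ``l`` whose eigenvalues
capture at least a fraction ``w`` of the total variance:

    l = min { l : (lambda_1 + ... + lambda_l) / (lambda_1 + ... + lambda_k) >= w }

Eigenvalues are those of the sample covariance matrix (divisor ``n - 1``) of
the mean-centered feature matrix; features are not rescaled.  When there are
fewer samples than features the eigendecomposition is done on the n x n Gram
matrix of the centered rows, which has the same nonzero spectrum; components
are recovered from the left singular vectors.  Each component's sign is fixed
so that its largest-magnitude coordinate is positive, making fitted models
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ShapeError


@dataclass(frozen=True)
class PcaModel:
    """Fitted PCA projection.

    Attributes
    ----------
    mean_vector
        Per-feature means of the training matrix, shape (k,).
    components
        Retained eigenvectors as rows, shape (l, k), orthonormal.
    eigenvalues
        Their covariance eigenvalues, non-increasing, shape (l,).
    total_variance
        Sum of all k covariance eigenvalues of the training data.
    w_threshold
        Cumulative-variance threshold used for selection.
    """

    mean_vector: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    w_threshold: float

    @property
    def k_original(self) -> int:
        return self.mean_vector.shape[0]

    @property
    def l_retained(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.k_original:
            raise ShapeError(
                f"matrix has {X.shape[1]} columns, model expects {self.k_original}"
            )
        return (X - self.mean_vector) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.l_retained:
            raise ShapeError(
                f"scores have {scores.shape[1]} columns, model has {self.l_retained}"
            )
        return scores @ self.components + self.mean_vector

    def score_names(self) -> tuple[str, ...]:
        return tuple(f"PC{i + 1}" for i in range(self.l_retained))

    def to_csv(self, path: str | Path) -> None:
        """Audit export: first row is the mean vector, then one row per PC."""
        frame = pd.DataFrame(
            np.vstack([self.mean_vector, self.components]),
            index=["mean"] + list(self.score_names()),
        )
        frame.insert(0, "eigenvalue", [np.nan] + list(self.eigenvalues))
        frame.to_csv(path, index_label="row")


def select_l(eigenvalues: np.ndarray, total: float, w: float) -> int:
    """Smallest l with cumulative eigenvalue mass >= w of ``total``."""
    cum = np.cumsum(eigenvalues)
    meets = np.flatnonzero(cum >= w * total - 1e-12 * abs(total))
    if meets.size == 0:
        return eigenvalues.shape[0]
    return int(meets[0]) + 1


def _fix_signs(components: np.ndarray) -> np.ndarray:
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return components * flip[:, None]


def fit_pca(X: np.ndarray, w: float = 0.99) -> PcaModel:
    """Fit the projection on a (n, k) matrix and select components by ``w``.

    Raises on fewer than two rows or an all-constant matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix, got shape {X.shape}")
    n, k = X.shape
    if n < 2:
        raise ValueError(f"PCA requires at least 2 rows, got {n}")
    if not 0.0 < w <= 1.0:
        raise ValueError(f"w must be in (0, 1], got {w}")

    mean = X.mean(axis=0)
    Xc = X - mean
    total = float(np.sum(Xc * Xc)) / (n - 1)
    if total <= 0.0:
        raise ValueError("zero total variance: all rows are identical")

    if n - 1 >= k:
        cov = Xc.T @ Xc / (n - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        components = eigvec[:, order].T
    else:
        # Gram route: same nonzero spectrum, components from left vectors
        gram = Xc @ Xc.T
        eigval_g, u = np.linalg.eigh(gram)
        order = np.argsort(eigval_g)[::-1]
        eigval_g = np.clip(eigval_g[order], 0.0, None)
        u = u[:, order]
        nonzero = eigval_g > eigval_g[0] * 1e-12 if eigval_g[0] > 0 else eigval_g > 0
        r = int(nonzero.sum())
        components = (Xc.T @ u[:, :r] / np.sqrt(eigval_g[:r])).T
        eigval = eigval_g / (n - 1)
        eigval[r:] = 0.0
        components = components  # rank-truncated

    l = select_l(eigval, total, w)
    l = min(l, components.shape[0])
    return PcaModel(
        mean_vector=mean,
        components=_fix_signs(np.ascontiguousarray(components[:l])),
        eigenvalues=eigval[:l].copy(),
        total_variance=total,
        w_threshold=float(w),
    )
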