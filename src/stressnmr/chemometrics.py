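"""From-scratch PCA and OPLS-DA with cross-validated quality metrics.

PCA (mean-centered) serves spectral quality verification; OPLS-DA (Pareto
scaled) serves two-group discrimination.  OPLS-DA splits the variation of
the binned matrix X into one component predictive of class membership and
``n_orth`` orthogonal (class-unrelated) components, and reports for every
bin the Pearson correlation r and covariance between the predictive score
and that bin — the "correlation loadings" that the significance cutoff is
later applied to.

Model quality is summarised by R2X (fraction of the scaled X variance the
components capture) and Q2 (cross-validated predictive ability of y,
1 - PRESS/SS), estimated with deterministic venetian-blind folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScalingSpec",
    "PcaModel",
    "OplsModel",
    "scale_columns",
    "fit_pca",
    "fit_oplsda",
    "cross_validated_q2",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateFoldError(ValueError):
    pass


@dataclass
class ScalingSpec:
    """Column scaling fitted on training rows.

    ``mean_center`` subtracts column means; ``pareto`` additionally divides
    by the square root of the column standard deviation, damping the
    dominance of intense bins while keeping some magnitude information.
    Zero-variance columns pass through centered with divisor 1.
    """

    kind: str
    column_means: np.ndarray
    column_sds: np.ndarray
    divisors: np.ndarray

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.column_means) / self.divisors


def scale_columns(matrix: np.ndarray, kind: str = "pareto") -> tuple[np.ndarray, ScalingSpec]:
    """Center (and for ``pareto``, sqrt-SD scale) the columns of a matrix.

    Standard deviations use the n-1 (sample) convention.  Columns with zero
    variance are centered but not divided, with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("need a 2-D matrix with at least 2 rows")
    if kind not in ("mean_center", "pareto"):
        raise ValueError(f"unknown scaling kind {kind!r}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if kind == "mean_center":
        divisors = np.ones_like(sds)
    else:
        zero = sds == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s) passed through "
                "centered with divisor 1",
                stacklevel=2,
            )
        divisors = np.where(zero, 1.0, np.sqrt(sds))
    spec = ScalingSpec(kind, means, sds, divisors)
    return spec.apply(X), spec


@dataclass
class PcaModel:
    """Principal components of a mean-centered matrix."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    mean_: np.ndarray = field(repr=False, default=None)


def fit_pca(matrix: np.ndarray, k: int) -> PcaModel:
    """Fit a k-component PCA by singular value decomposition.

    Components successively maximise residual variance; ``scores`` is the
    centered matrix projected on the orthonormal ``loadings``.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    frac = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return PcaModel(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance_fraction=frac,
        mean_=mean,
    )


@dataclass
class OplsModel:
    """Fitted OPLS-DA state for a two-group design.

    The predictive score ``t_pred`` is oriented so that the case group's
    mean score is positive; a positive correlation loading therefore means
    "elevated in the case (stressed) group".
    """

    t_pred: np.ndarray
    p_pred: np.ndarray
    w_pred: np.ndarray
    t_orth: np.ndarray  # samples x n_orth
    p_orth: np.ndarray  # bins x n_orth
    w_orth: np.ndarray  # bins x n_orth
    n_orth: int
    r2x: float
    corr_loadings: np.ndarray
    cov_loadings: np.ndarray
    scaling: ScalingSpec
    b_: float = 0.0  # inner regression coefficient of y on t_pred
    y_mean_: float = 0.0
    classes_: tuple[str, str] = ("control", "case")  # (negative, positive)
    q2: float | None = None

    def predict_scores(self, matrix: np.ndarray) -> np.ndarray:
        """Predictive scores of new samples (orthogonal structure removed)."""
        X = self.scaling.apply(np.asarray(matrix, dtype=float))
        for j in range(self.n_orth):
            t_o = X @ self.w_orth[:, j]
            X = X - np.outer(t_o, self.p_orth[:, j])
        return X @ self.w_pred

    def predict_y(self, matrix: np.ndarray) -> np.ndarray:
        """Continuous class prediction on the +/-1 encoding scale."""
        return self.predict_scores(matrix) * self.b_ + self.y_mean_


def _encode_labels(
    labels: Sequence[str], positive_label: str | None
) -> tuple[np.ndarray, tuple[str, str]]:
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(
            f"OPLS-DA supports exactly two classes, got {len(classes)}: {classes}"
        )
    if positive_label is None:
        positive_label = "case" if "case" in classes else classes[1]
    if positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {classes}")
    negative_label = next(c for c in classes if c != positive_label)
    y = np.array([1.0 if lab == positive_label else -1.0 for lab in labels])
    return y, (negative_label, positive_label)


def fit_oplsda(
    matrix: np.ndarray,
    labels: Sequence[str],
    n_orth: int = 1,
    scaling: str = "pareto",
    positive_label: str | None = None,
) -> OplsModel:
    """Fit an OPLS-DA model with one predictive and ``n_orth`` orthogonal
    components.

    The class membership is encoded +/-1 and centered.  The predictive
    weight is ``w = X'y / (y'y)`` normalised; each orthogonal component is
    extracted from the current loading's part orthogonal to ``w`` and
    deflated from X; the predictive component is then computed from the
    deflated matrix.  Correlation/covariance loadings are computed against
    the scaled but *undeflated* matrix so they read as metabolite-vs-class
    correlations.
    """
    X_raw = np.asarray(matrix, dtype=float)
    y_enc, classes = _encode_labels(labels, positive_label)
    for cls in classes:
        if sum(1 for lab in labels if lab == cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    if np.all(y_enc == y_enc[0]):
        raise ValueError("labels are constant")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")

    Xs, spec = scale_columns(X_raw, scaling)
    X0 = Xs.copy()
    y = y_enc - y_enc.mean()

    w = Xs.T @ y / (y @ y)
    w_norm = np.linalg.norm(w)
    if w_norm < 1e-300:
        # no covariance between X and y at all (e.g. constant X): the model
        # degenerates to predicting the class mean
        w = np.zeros_like(w)
    else:
        w = w / w_norm

    t_orth = np.zeros((Xs.shape[0], n_orth))
    p_orth = np.zeros((Xs.shape[1], n_orth))
    w_orth = np.zeros((Xs.shape[1], n_orth))
    X = Xs.copy()
    degenerate = w_norm < 1e-300
    for j in range(n_orth if not degenerate else 0):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            # no orthogonal variation left; keep zero component
            break
        w_o = w_o / norm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        t_orth[:, j], p_orth[:, j], w_orth[:, j] = t_o, p_o, w_o

    t_pred = X @ w
    if degenerate:
        p_pred = np.zeros_like(w)
        b = 0.0
    else:
        p_pred = X.T @ t_pred / (t_pred @ t_pred)
        # orient so the positive class has positive mean predictive score
        if t_pred[y_enc > 0].mean() < 0:
            w, t_pred, p_pred = -w, -t_pred, -p_pred
        b = float(t_pred @ y / (t_pred @ t_pred))

    model_part = np.outer(t_pred, p_pred) + t_orth @ p_orth.T
    ss_total = float(np.sum(X0**2))
    r2x = float(np.sum(model_part**2) / ss_total) if ss_total > 0 else 0.0
    r2x = min(max(r2x, 0.0), 1.0)

    # correlation/covariance of t_pred with each column of the undeflated matrix
    tc = t_pred - t_pred.mean()
    Xc = X0 - X0.mean(axis=0)
    n = X0.shape[0]
    cov = Xc.T @ tc / (n - 1)
    t_sd = np.sqrt(tc @ tc / (n - 1))
    col_sd = np.sqrt(np.sum(Xc**2, axis=0) / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(col_sd > 0, cov / (t_sd * col_sd), 0.0)
    corr = np.clip(corr, -1.0, 1.0)

    return OplsModel(
        t_pred=t_pred,
        p_pred=p_pred,
        w_pred=w,
        t_orth=t_orth,
        p_orth=p_orth,
        w_orth=w_orth,
        n_orth=n_orth,
        r2x=r2x,
        corr_loadings=corr,
        cov_loadings=cov,
        scaling=spec,
        b_=b,
        y_mean_=float(y_enc.mean()),
        classes_=classes,
    )


def venetian_blind_folds(n_samples: int, folds: int) -> list[np.ndarray]:
    """Deterministic interleaved folds: fold k holds samples k, k+folds, ..."""
    return [np.arange(k, n_samples, folds) for k in range(folds)]


def cross_validated_q2(
    matrix: np.ndarray,
    labels: Sequence[str],
    n_orth: int = 1,
    folds: int = 7,
    scaling: str = "pareto",
    positive_label: str | None = None,
) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/SS(y centered).

    Venetian-blind (interleaved-by-index) folds; the scaling and the model
    are refit on every training split so no information leaks from held-out
    samples.  Q2 is at most 1; a model no better than predicting the
    training mean scores 0, and worse models go negative.
    """
    X = np.asarray(matrix, dtype=float)
    labels = list(labels)
    n = X.shape[0]
    if not 2 <= folds <= n:
        raise ValueError("folds must be between 2 and the number of samples")
    y_enc, _ = _encode_labels(labels, positive_label)

    y_hat = np.full(n, np.nan)
    for k, test_idx in enumerate(venetian_blind_folds(n, folds)):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_labels = [labels[i] for i in np.flatnonzero(train_mask)]
        if len(set(train_labels)) < 2:
            raise DegenerateFoldError(
                f"fold {k} leaves a single-class training set"
            )
        model = fit_oplsda(
            X[train_mask], train_labels, n_orth=n_orth, scaling=scaling,
            positive_label=positive_label,
        )
        y_hat[test_idx] = model.predict_y(X[test_idx])

    press = float(np.sum((y_enc - y_hat) ** 2))
    ss = float(np.sum((y_enc - y_enc.mean()) ** 2))
    return 1.0 - press / ss
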