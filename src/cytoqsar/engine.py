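"""Single-model training: self-consistent variable selection + RBF regression.

A single QSAR model is trained in two stages:

1. **Selection** (:func:`scr_select`): ridge regression with backward
   elimination.  At each step the column with the least significant weight
   (smallest ``|w|/se``) is dropped; the retained subset is the one that
   maximised the closed-form leave-one-out Q**2 along the elimination path.
2. **RBF stage** (:func:`rbf_fit`): a Gaussian radial-basis-function network
   on the selected columns, with every training row as a center, kernel
   width set to the median pairwise distance, and output weights from
   ridge-regularised least squares.

The linear stage uses a penalised-intercept formulation (a constant column
inside the design matrix, subject to the same ridge penalty), which makes
the hat-matrix leave-one-out identity exact:  e_loo_i = e_i / (1 - H_ii).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .chem import MoleculeGraph
from .descriptors import DescriptorConfig, Featurizer

logger = logging.getLogger(__name__)

__all__ = [
    "SingleModel",
    "ridge_weights",
    "ridge_loo_residuals",
    "loo_q2",
    "scr_select",
    "rbf_fit",
    "krr_loo_residuals",
    "predict_single",
    "train_single_model",
]

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0)
MIN_TRAIN_SIZE = 10


def _augment(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(x)), x])


def ridge_weights(xa: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge solution on an already-augmented design matrix."""
    d = xa.shape[1]
    return np.linalg.solve(xa.T @ xa + lam * np.eye(d), xa.T @ y)


def ridge_loo_residuals(xa: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Exact leave-one-out residuals of penalised least squares.

    Uses the hat-matrix identity e_loo_i = e_i / (1 - H_ii) with
    H = X (X'X + lam I)^-1 X'; exact because lam and the column set are held
    fixed when row i is removed.
    """
    d = xa.shape[1]
    g = np.linalg.solve(xa.T @ xa + lam * np.eye(d), xa.T)  # (d, n)
    h_diag = np.einsum("ij,ji->i", xa, g)
    resid = y - xa @ (g @ y)
    return resid / (1.0 - h_diag)


def loo_q2(y: np.ndarray, loo_resid: np.ndarray) -> float:
    """Cross-validated R**2 from leave-one-out residuals (0 if y is constant)."""
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        return 0.0
    return 1.0 - float(np.sum(loo_resid**2)) / tss


def scr_select(
    x: np.ndarray,
    y: np.ndarray,
    lam: float = 0.1,
    min_features: int = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Backward-elimination variable selection scored by leave-one-out Q**2.

    Repeatedly fits ridge regression, drops the column with the smallest
    ``|weight| / standard-error``, and finally returns the subset that gave
    the highest LOO Q**2 along the path, with its linear weights (intercept
    first).  Deterministic given (x, y, lam).

    Returns (selected column indices, weights, best LOO Q**2).
    """
    n, d = x.shape
    if n < MIN_TRAIN_SIZE:
        raise ValueError(f"need at least {MIN_TRAIN_SIZE} rows to train, got {n}")
    if d < 1:
        raise ValueError("need at least one feature column")
    active = list(range(d))
    best_q2 = -np.inf
    best_subset: list[int] = active.copy()
    best_w: np.ndarray | None = None
    while True:
        xa = _augment(x[:, active])
        w = ridge_weights(xa, y, lam)
        q2 = loo_q2(y, ridge_loo_residuals(xa, y, lam))
        if q2 > best_q2 + 1e-12:
            best_q2, best_subset, best_w = q2, active.copy(), w
        if len(active) <= min_features:
            break
        # |w|/se on the non-intercept columns; se from the ridge sandwich
        da = xa.shape[1]
        ginv = np.linalg.inv(xa.T @ xa + lam * np.eye(da))
        resid = y - xa @ w
        dof = max(n - da, 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * (ginv @ (xa.T @ xa) @ ginv)
        se = np.sqrt(np.maximum(np.diag(cov), 1e-30))
        tstat = np.abs(w[1:]) / se[1:]
        drop_local = int(np.argmin(tstat))
        active.pop(drop_local)
    assert best_w is not None
    return np.asarray(best_subset, dtype=int), best_w, float(best_q2)


# ---------------------------------------------------------------------------
# RBF stage


def _gaussian_kernel(a: np.ndarray, b: np.ndarray, width: float) -> np.ndarray:
    d2 = cdist(a, b, "sqeuclidean")
    return np.exp(-0.5 * d2 / width**2)


def median_pairwise_width(x: np.ndarray, fallback: float = 1.0) -> float:
    if len(x) < 2:
        return fallback
    w = float(np.median(pdist(x)))
    if w <= 1e-12:
        logger.warning("kernel width underflow; falling back to %.1f", fallback)
        return fallback
    return w


def krr_loo_residuals(k: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Leave-one-out residuals of kernel ridge regression.

    e_loo_i = e_i / (1 - H_ii) with H = K (K + lam I)^-1; exact for a fixed
    kernel width and target offset, because deleting row i of the KRR system
    also deletes center i.
    """
    n = len(y)
    g = np.linalg.solve(k + lam * np.eye(n), np.eye(n))
    h = k @ g
    resid = y - h @ y
    return resid / (1.0 - np.diag(h))


@dataclass
class SingleModel:
    """One trained variable-selected RBF regressor."""

    config: DescriptorConfig
    featurizer: Featurizer
    selected: np.ndarray            # column indices into featurizer output
    selected_labels: tuple[str, ...]
    linear_weights: np.ndarray      # intercept-first ridge weights (audit)
    scr_lambda: float
    centers: np.ndarray             # training rows in the reduced space
    width: float
    alpha: np.ndarray               # RBF output weights
    offset: float                   # target offset (training mean)
    rbf_lambda: float
    r2_train: float = np.nan
    q2_loo: float = np.nan
    r2_lmo: float = np.nan
    train_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def predict_reduced(self, x_reduced: np.ndarray) -> np.ndarray:
        k = _gaussian_kernel(x_reduced, self.centers, self.width)
        return self.offset + k @ self.alpha

    def predict_features(self, x_full: np.ndarray) -> np.ndarray:
        return self.predict_reduced(x_full[:, self.selected])

    def predict_molecules(self, mols: list[MoleculeGraph]) -> np.ndarray:
        return self.predict_features(self.featurizer.transform(mols))

    def leverage(self, x_full: np.ndarray) -> np.ndarray:
        """Hat values of query rows in this model's reduced linear space."""
        xr = x_full[:, self.selected]
        xa = _augment(self.centers)
        ginv = np.linalg.inv(xa.T @ xa + self.scr_lambda * np.eye(xa.shape[1]))
        qa = _augment(xr)
        return np.einsum("ij,jk,ik->i", qa, ginv, qa)

    @property
    def leverage_threshold(self) -> float:
        p = len(self.selected)
        return 3.0 * (p + 1) / len(self.centers)


def rbf_fit(
    x_reduced: np.ndarray,
    y: np.ndarray,
    lam_out: float,
    width: float | None = None,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Fit the RBF output layer; returns (centers, width, alpha, offset)."""
    if width is None:
        width = median_pairwise_width(x_reduced)
    offset = float(y.mean())
    k = _gaussian_kernel(x_reduced, x_reduced, width)
    alpha = np.linalg.solve(k + lam_out * np.eye(len(y)), y - offset)
    return x_reduced.copy(), width, alpha, offset


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


def _lmo_r2(
    x_reduced: np.ndarray,
    y: np.ndarray,
    lam_out: float,
    width: float,
    n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Internal leave-many-out score: 20% held out, repeated n_splits times."""
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_splits)
    pred = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(order, fold)
        offset = float(y[train].mean())
        k = _gaussian_kernel(x_reduced[train], x_reduced[train], width)
        alpha = np.linalg.solve(k + lam_out * np.eye(len(train)), y[train] - offset)
        kq = _gaussian_kernel(x_reduced[fold], x_reduced[train], width)
        pred[fold] = offset + kq @ alpha
    return _r2(y, pred)


def train_single_model(
    molecules: list[MoleculeGraph],
    y: np.ndarray,
    config: DescriptorConfig,
    scr_lambda: float = 0.1,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    min_features: int = 5,
    seed: int = 0,
    train_rows: np.ndarray | None = None,
) -> SingleModel:
    """Full single-model pipeline: featurize, select, fit, score.

    The RBF ridge penalty is chosen from ``lambda_grid`` by the internal
    leave-many-out score.  Training statistics (R**2 train, LOO Q**2, LMO
    R**2) are stored on the model.
    """
    y = np.asarray(y, dtype=float)
    feat = Featurizer(config=config).fit(molecules)
    x = feat.transform(molecules)
    selected, weights, _ = scr_select(x, y, lam=scr_lambda, min_features=min_features)
    xr = x[:, selected]
    width = median_pairwise_width(xr)

    best = None
    for lam_out in lambda_grid:
        score = _lmo_r2(xr, y, lam_out, width, seed=seed)
        if best is None or score > best[0] + 1e-12:
            best = (score, lam_out)
    assert best is not None
    r2_lmo, lam_out = best

    centers, width, alpha, offset = rbf_fit(xr, y, lam_out, width=width)
    k = _gaussian_kernel(xr, centers, width)
    yhat = offset + k @ alpha
    q2 = loo_q2(y - offset, krr_loo_residuals(k, y - offset, lam_out))

    labels = tuple(feat.labels[i] for i in selected)
    return SingleModel(
        config=config,
        featurizer=feat,
        selected=selected,
        selected_labels=labels,
        linear_weights=weights,
        scr_lambda=scr_lambda,
        centers=centers,
        width=width,
        alpha=alpha,
        offset=offset,
        rbf_lambda=lam_out,
        r2_train=_r2(y, yhat),
        q2_loo=q2,
        r2_lmo=r2_lmo,
        train_rows=train_rows if train_rows is not None else np.arange(len(y)),
    )


def predict_single(model: SingleModel, mol: MoleculeGraph) -> float:
    """Deterministic scalar prediction for one molecule."""
    value = float(model.predict_molecules([mol])[0])
    if not np.isfinite(value):
        raise ValueError("non-finite prediction")
    return value
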