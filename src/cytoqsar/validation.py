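"""Model quality metrics and cross-validation protocols.

The coefficient of determination and root-mean-square error are

    R**2 = 1 - sum((y_exp - y_pred)**2) / sum((y_exp - y_mean)**2)
    RMSE = sqrt(sum((y_exp - y_pred)**2) / n)

with y_mean the mean experimental value.  Negative R**2 is reported as-is.
5-fold cross-validation refits the **full** pipeline (descriptor vocabulary,
scalers, ensemble, selection) on each 80% split and pools the out-of-fold
predictions; a final model is accepted when the pooled statistics satisfy
R**2 > 0.5 and RMSE < 1 (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .activity import TrainingSet

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "r_squared",
    "rmse",
    "q2_loo",
    "kfold_cv",
    "accept_final",
    "recover_fragment_contributions",
]


def _check_lengths(y_exp: Sequence[float], y_pred: Sequence[float], minimum: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_exp, dtype=float)
    b = np.asarray(y_pred, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < minimum:
        raise ValueError(f"need at least {minimum} values")
    return a, b


def r_squared(y_exp: Sequence[float], y_pred: Sequence[float]) -> float:
    """Coefficient of determination; 0 under the zero-variance guard."""
    a, b = _check_lengths(y_exp, y_pred, 2)
    tss = float(np.sum((a - a.mean()) ** 2))
    if tss <= 0:
        return 0.0
    return 1.0 - float(np.sum((a - b) ** 2)) / tss


def rmse(y_exp: Sequence[float], y_pred: Sequence[float]) -> float:
    a, b = _check_lengths(y_exp, y_pred, 1)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def q2_loo(ts: TrainingSet, config=None, scr_lambda: float = 0.1) -> float:
    """Leave-one-out Q**2 of a single model trained on the full set.

    Uses the hat-matrix shortcut of the kernel-ridge stage, whose
    equivalence to explicit refitting is covered by the engine's oracle
    tests.
    """
    from .descriptors import DescriptorConfig
    from .engine import train_single_model

    if config is None:
        config = DescriptorConfig()
    model = train_single_model(ts.molecules(), np.asarray(ts.p_values()), config, scr_lambda=scr_lambda)
    return model.q2_loo


@dataclass
class ValidationReport:
    n: int
    r2: float
    rmse: float
    protocol: str  # "train" | "LOO" | "LMO" | "5-fold"
    seed: int
    fold_assignment: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    per_fold: list[dict] = field(default_factory=list)
    oof_predictions: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_exp: np.ndarray = field(default_factory=lambda: np.empty(0))
    available: bool = True  # False when a fold produced no acceptable model


def kfold_cv(
    ts: TrainingSet,
    build_fn: Callable[[TrainingSet], object | None],
    k: int = 5,
    seed: int = 0,
) -> ValidationReport:
    """k-fold cross-validation with full per-fold pipeline refits.

    ``build_fn(training subset) -> model with .predict_molecule(mol)`` (or
    None when no acceptable model can be built, which marks the whole report
    "not available").  Folds are a seeded random partition into near-equal
    parts; metrics are pooled over the out-of-fold predictions.
    """
    n = ts.n
    if n < k:
        raise ValueError(f"need at least k={k} compounds, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold_id, fold in enumerate(np.array_split(order, k)):
        assignment[fold] = fold_id

    y = np.asarray(ts.p_values())
    oof = np.full(n, np.nan)
    per_fold: list[dict] = []
    for fold_id in range(k):
        test_idx = np.flatnonzero(assignment == fold_id)
        train_idx = np.flatnonzero(assignment != fold_id)
        sub = TrainingSet(
            cell_line=ts.cell_line,
            endpoint=ts.endpoint,
            entries=tuple(ts.entries[i] for i in train_idx),
            tissue=ts.tissue,
            tumor=ts.tumor,
        )
        model = build_fn(sub)
        if model is None:
            logger.warning(
                "%s/%s fold %d: no acceptable model; 5-fold CV not available",
                ts.cell_line, ts.endpoint, fold_id,
            )
            return ValidationReport(
                n=n, r2=np.nan, rmse=np.nan, protocol=f"{k}-fold", seed=seed,
                fold_assignment=assignment, per_fold=per_fold, available=False,
            )
        preds = np.array([model.predict_molecule(ts.entries[i][1]) for i in test_idx])
        oof[test_idx] = preds
        per_fold.append(
            {
                "fold": fold_id,
                "n_test": len(test_idx),
                "r2": r_squared(y[test_idx], preds) if len(test_idx) >= 2 else np.nan,
                "rmse": rmse(y[test_idx], preds),
            }
        )
    return ValidationReport(
        n=n,
        r2=r_squared(y, oof),
        rmse=rmse(y, oof),
        protocol=f"{k}-fold",
        seed=seed,
        fold_assignment=assignment,
        per_fold=per_fold,
        oof_predictions=oof,
        y_exp=y,
    )


def accept_final(report: ValidationReport, r2_min: float = 0.5, rmse_max: float = 1.0) -> bool:
    """Final-model acceptance: R**2 strictly above r2_min AND RMSE strictly below rmse_max."""
    if not report.available:
        return False
    return bool(report.r2 > r2_min and report.rmse < rmse_max)


def recover_fragment_contributions(
    design: np.ndarray,
    y: Sequence[float],
    lam: float = 1e-6,
) -> np.ndarray:
    """Estimate additive fragment contributions from indicator columns.

    Ridge regression (tiny penalty to absorb the exact collinearity of
    one-hot groups) of the observed activities on fragment indicator
    columns, intercept included.  Contributions are identified only up to a
    per-group constant, so callers should compare group-centered values.
    """
    x = np.asarray(design, dtype=float)
    yv = np.asarray(y, dtype=float)
    xa = np.column_stack([np.ones(len(x)), x])
    w = np.linalg.solve(xa.T @ xa + lam * np.eye(xa.shape[1]), xa.T @ yv)
    return w[1:]
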