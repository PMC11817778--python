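"""Calibration metrics (R², RMSE, RMSECV) and report assembly.

Conventions: R² = 1 − SS_res/SS_tot (not squared Pearson correlation);
RMSEC/RMSEP are the root-mean-square errors on the calibration and prediction
partitions; RMSECV pools out-of-fold residuals from k-fold cross-validation,
with folds formed as contiguous blocks of a seeded shuffle so that every model
compared in one experiment sees the same fold map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, ReportError


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 − Σ(y−ŷ)²/Σ(y−ȳ)²."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise DimensionError("y_true and y_pred have different lengths")
    if y_true.size < 2:
        raise DimensionError("R^2 needs at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroDivisionError("R^2 undefined: y_true is constant")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error, in the units of y (mass % for fractions)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise DimensionError("y_true and y_pred have different lengths")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def kfold_indices(n: int, folds: int, seed: int = 0) -> np.ndarray:
    """Fold id per sample: contiguous blocks of a seeded shuffle."""
    if folds < 2 or folds > n:
        raise DimensionError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    order = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, block in enumerate(np.array_split(order, folds)):
        fold_of[block] = f
    return fold_of


def cross_val_rmse(fit_fn, X, y, folds: int = 5, seed: int = 0,
                   fold_ids: np.ndarray | None = None) -> float:
    """Pooled out-of-fold RMSE.

    ``fit_fn(X_train, y_train)`` must return an object with ``predict``.
    Residuals from every fold are pooled before the square root:
    ``sqrt(Σ_i (y_i − ŷ_i^(−fold(i)))² / n)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = y.size
    fold_of = kfold_indices(n, folds, seed) if fold_ids is None else np.asarray(fold_ids)
    pred = np.empty(n)
    for f in np.unique(fold_of):
        test = fold_of == f
        train = ~test
        try:
            model = fit_fn(X[train], y[train])
        except Exception as exc:  # noqa: BLE001 - annotate which fold failed
            raise RuntimeError(f"cross-validation fold {f} failed to fit") from exc
        pred[test] = np.asarray(model.predict(X[test])).ravel()
    return float(np.sqrt(np.mean((y - pred) ** 2)))


# ------------------------------------------------------------------ reports

REPORT_COLUMNS = ["target", "model", "params", "RC2", "RMSEC", "RP2", "RMSEP", "RMSECV"]


@dataclass
class EvalReport:
    """One Table-row worth of results for a (target, model) cell."""

    target: str
    model: str
    params: str
    RC2: float
    RMSEC: float
    RP2: float
    RMSEP: float
    RMSECV: float = float("nan")


def build_report(models: dict, data, split, target: str,
                 rmsecv: dict | None = None) -> list[EvalReport]:
    """Score fitted models for one target on a calibration/prediction split.

    Parameters
    ----------
    models
        Mapping ``label -> (fitted_model, params_string)`` where the fitted
        model exposes ``predict(X)``.  ``data`` must already be restricted to
        whatever variable subset the models were trained on.
    data
        The (preprocessed) :class:`SpectraSet` covering all samples.
    split
        A :class:`~nirquant.sampling.KSSplit`.
    target
        ``"A"``, ``"B"`` or ``"C"`` (or the ``fA``/``fB``/``fC`` forms).

    Calibration metrics use only calibration rows; prediction metrics only
    prediction rows — there is no pathway for prediction-set values to enter
    the calibration-side numbers.
    """
    if not models:
        raise ReportError("no models to report")
    y = data.target(target)
    tr, te = np.asarray(split.train_indices), np.asarray(split.test_indices)
    rows = []
    for label, (model, params) in models.items():
        yhat_tr = np.asarray(model.predict(data.absorbance[tr])).ravel()
        yhat_te = np.asarray(model.predict(data.absorbance[te])).ravel()
        rows.append(EvalReport(
            target=target, model=label, params=params,
            RC2=r_squared(y[tr], yhat_tr), RMSEC=rmse(y[tr], yhat_tr),
            RP2=r_squared(y[te], yhat_te), RMSEP=rmse(y[te], yhat_te),
            RMSECV=(rmsecv or {}).get(label, float("nan")),
        ))
    return rows


def report_frame(rows: list[EvalReport]) -> pd.DataFrame:
    """Stack EvalReport rows into the Table-shaped DataFrame."""
    if not rows:
        raise ReportError("empty report")
    return pd.DataFrame([r.__dict__ for r in rows], columns=REPORT_COLUMNS)
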