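"""Calibration models (PLSR, PCR, SVR) and their evaluation metrics.

Model quality is reported the way NIR calibration tables are laid out:
RC2/RMSEC on the calibration fit, RCV2/RMSECV under cross-validation, and
RP2/RMSEP on the held-out prediction set, plus the retained component count.

R2 defaults to the squared Pearson correlation between measured and
predicted values (the standard RC2/RP2 of chemometrics). A printed-formula
variant — an unsquared cross-product over the *sum* of the two sums of
squares — circulates in parts of the applied literature; it is available
via ``formula="printed"`` for comparison but is not a coefficient of
determination (it cannot reach 1 unless the two spreads coincide) and is
never used internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._pls import PLSCoefficients, pls_cv_predictions, pls_fit
from .containers import SpectraMatrix
from .errors import (
    ConfigurationError,
    ContractError,
    RankError,
    SchemeError,
    UndefinedStatisticError,
)

__all__ = [
    "RegressionModel",
    "EvaluationReport",
    "CVResult",
    "fit",
    "predict",
    "r_squared",
    "rmse",
    "cross_validate",
    "evaluate_grid",
    "MAX_COMPONENTS",
]

MAX_COMPONENTS = 15

_SVM_GRID = {
    "svr__C": [1.0, 10.0, 100.0],
    "svr__gamma": ["scale", 0.1, 1.0],
    "svr__epsilon": [0.01, 0.1],
}


@dataclass
class RegressionModel:
    """A fitted calibration: linear coefficient form or an SVR estimator."""

    kind: str  # {plsr, pcr, svmr}
    wavelengths: np.ndarray  # training band axis
    n_components: int | None = None
    coef_: np.ndarray | None = None  # linear kinds, original-X scale
    intercept_: float | None = None
    estimator: object | None = None  # svmr

    def _check_axis(self, wavelengths: np.ndarray) -> None:
        if len(wavelengths) != len(self.wavelengths) or not np.allclose(
            wavelengths, self.wavelengths
        ):
            raise ContractError("band axis does not match the training wavelengths")


def _as_xy(x, y=None):
    if isinstance(x, SpectraMatrix):
        values, wl = x.values, x.wavelengths
    else:
        values = np.atleast_2d(np.asarray(x, dtype=float))
        wl = np.arange(values.shape[1], dtype=float)
    if y is None:
        return values, wl
    return values, wl, np.asarray(y, dtype=float).ravel()


def fit(
    kind: str,
    x: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    svm_params: dict | None = None,
    seed: int = 0,
) -> RegressionModel:
    """Fit a PLSR, PCR, or SVR calibration.

    PLSR is NIPALS with mean-centring (no variance scaling; pretreatment
    owns the scale). PCR projects centred X onto its leading principal
    components and regresses y on the scores. SVR uses an RBF kernel; when
    ``svm_params`` is not given, hyperparameters come from a seeded internal
    5-fold grid search.
    """
    values, wl, yv = _as_xy(x, y)
    n, p = values.shape
    if not np.all(np.isfinite(yv)):
        raise ConfigurationError("y contains non-finite values")
    if yv.size != n:
        raise ConfigurationError("y length does not match the sample count")

    if kind == "plsr":
        a = n_components or min(MAX_COMPONENTS, n - 1, p)
        if a > min(n - 1, p):
            raise RankError(f"{a} components exceed the achievable rank")
        coef = pls_fit(values, yv, a)
        if coef.n_components < a and n_components is not None:
            raise RankError(
                f"NIPALS exhausted at {coef.n_components} < {a} components"
            )
        b = coef.coefs[min(a, coef.n_components) - 1]
        return RegressionModel(
            kind="plsr",
            wavelengths=wl,
            n_components=min(a, coef.n_components),
            coef_=b,
            intercept_=float(coef.y_mean - coef.x_mean @ b),
        )
    if kind == "pcr":
        a = n_components or min(MAX_COMPONENTS, n - 1, p)
        xm = values.mean(axis=0)
        xc = values - xm
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        if a > rank:
            raise RankError(f"{a} components exceed rank {rank}")
        scores = u[:, :a] * s[:a]
        gamma, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), scores]), yv, rcond=None
        )
        b = vt[:a].T @ gamma[1:]
        return RegressionModel(
            kind="pcr",
            wavelengths=wl,
            n_components=a,
            coef_=b,
            intercept_=float(gamma[0] - xm @ b),
        )
    if kind == "svmr":
        pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
        if svm_params:
            pipe.set_params(**{f"svr__{k}": v for k, v in svm_params.items()})
            est = pipe.fit(values, yv)
        else:
            cv = KFold(n_splits=min(5, n), shuffle=True, random_state=seed)
            search = GridSearchCV(pipe, _SVM_GRID, cv=cv, scoring="neg_root_mean_squared_error")
            est = search.fit(values, yv).best_estimator_
        return RegressionModel(kind="svmr", wavelengths=wl, estimator=est)
    raise ConfigurationError(f"unknown model kind {kind!r}")


def predict(model: RegressionModel, x: SpectraMatrix | np.ndarray) -> np.ndarray:
    values, wl = _as_xy(x)
    model._check_axis(wl)
    if model.kind in ("plsr", "pcr"):
        return values @ model.coef_ + model.intercept_
    return model.estimator.predict(values)


# ------------------------------------------------------------------ metrics


def r_squared(actual, predicted, formula: str = "pearson") -> float:
    """Coefficient of determination between measured and predicted values.

    ``formula="pearson"`` (default): squared Pearson correlation, in [0, 1].
    ``formula="printed"``: the literal cross-product / (SSx + SSy) variant;
    kept only for comparison (see module docstring).
    """
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size or a.size < 2:
        raise ConfigurationError("actual/predicted must have equal lengths >= 2")
    ac = a - a.mean()
    if np.allclose(ac, 0):
        raise UndefinedStatisticError("R^2 undefined for constant actual values")
    pc = p - p.mean()
    if formula == "printed":
        return float((ac @ pc) / (ac @ ac + pc @ pc))
    if formula != "pearson":
        raise ConfigurationError(f"unknown R^2 formula {formula!r}")
    denom = float(np.sqrt((ac @ ac) * (pc @ pc)))
    if denom == 0:  # constant predictions: no linear association
        return 0.0
    r = float(ac @ pc) / denom
    return min(r * r, 1.0)


def rmse(actual, predicted) -> float:
    """Root-mean-square error, in the units of y."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size or a.size < 1:
        raise ConfigurationError("actual/predicted must have equal lengths >= 1")
    return float(np.sqrt(np.mean((a - p) ** 2)))


# --------------------------------------------------------- cross-validation


@dataclass
class CVResult:
    best_components: int | None
    rcv2: float
    rmsecv: float
    rmsecv_by_components: np.ndarray | None = None
    predictions: np.ndarray | None = None


def _make_folds(n: int, scheme: str, k: int, seed: int) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        if not 2 <= k <= n:
            raise SchemeError(f"k={k} infeasible for n={n}")
        rng = np.random.default_rng(seed)
        return [f for f in np.array_split(rng.permutation(n), k)]
    raise ConfigurationError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    kind: str,
    x: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    scheme: str = "loo",
    k: int = 10,
    components_grid: Sequence[int] | None = None,
    seed: int = 0,
) -> CVResult:
    """Out-of-fold RMSECV over a component grid; best = minimal RMSECV.

    For PLSR/PCR each fold is fitted once at the maximal component count and
    per-component predictions are extracted; for SVR (no components) the
    out-of-fold RMSE of the grid-searched estimator is reported.
    """
    values, wl, yv = _as_xy(x, y)
    n = values.shape[0]
    folds = _make_folds(n, scheme, k, seed)
    if any(n - len(f) < 2 for f in folds):
        raise SchemeError("a fold leaves fewer than 2 training samples")

    if kind == "svmr":
        # hyperparameters are grid-searched once on the full calibration set,
        # then held fixed across folds (refitting the search per fold is
        # prohibitively slow under LOO and changes results negligibly)
        base = fit("svmr", values, yv, seed=seed)
        params = {
            k: v
            for k, v in base.estimator.get_params().items()
            if k in ("svr__C", "svr__gamma", "svr__epsilon")
        }
        preds = np.empty(n)
        for held in folds:
            train = np.setdiff1d(np.arange(n), held)
            est = Pipeline(
                [("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))]
            ).set_params(**params)
            est.fit(values[train], yv[train])
            preds[held] = est.predict(values[held])
        return CVResult(None, r_squared(yv, preds), rmse(yv, preds), None, preds)

    n_train_min = n - max(len(f) for f in folds)
    cap = max(1, min(MAX_COMPONENTS, n_train_min - 1, values.shape[1]))
    grid = list(components_grid) if components_grid else list(range(1, cap + 1))
    if not grid or max(grid) > cap:
        raise SchemeError(f"component grid exceeds the achievable cap {cap}")

    if kind == "plsr":
        all_preds = pls_cv_predictions(values, yv, max(grid), folds)
    elif kind == "pcr":
        all_preds = np.empty((n, max(grid)))
        for held in folds:
            train = np.setdiff1d(np.arange(n), held)
            xm = values[train].mean(axis=0)
            xc = values[train] - xm
            u, s, vt = np.linalg.svd(xc, full_matrices=False)
            for a in range(1, max(grid) + 1):
                scores = u[:, :a] * s[:a]
                gamma, *_ = np.linalg.lstsq(
                    np.column_stack([np.ones(len(train)), scores]), yv[train], rcond=None
                )
                b = vt[:a].T @ gamma[1:]
                all_preds[held, a - 1] = (values[held] - xm) @ b + gamma[0]
    else:
        raise ConfigurationError(f"unknown model kind {kind!r}")

    errs = np.array([rmse(yv, all_preds[:, a - 1]) for a in grid])
    best_pos = int(np.argmin(errs))
    best_a = grid[best_pos]
    preds = all_preds[:, best_a - 1]
    return CVResult(best_a, r_squared(yv, preds), float(errs[best_pos]), errs, preds)


# ------------------------------------------------------------------- report


class EvaluationReport:
    """Per-model metric table (the calibration-comparison layout)."""

    COLUMNS = ["model", "bands", "PCs", "RC2", "RMSEC", "RCV2", "RMSECV", "RP2", "RMSEP"]

    def __init__(self, rows: list[dict]):
        self.table = pd.DataFrame(rows)
        for col in self.COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        self.table = self.table[self.COLUMNS]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self, path=None) -> str:
        md = self.table.to_markdown(index=False, floatfmt=".4f")
        if path is not None:
            from pathlib import Path

            Path(path).write_text(md + "\n")
        return md

    def best(self, by: str = "RMSEP") -> pd.Series:
        return self.table.loc[self.table[by].idxmin()]


def evaluate_grid(
    xcal: SpectraMatrix,
    ycal: np.ndarray,
    xpred: SpectraMatrix,
    ypred: np.ndarray,
    selections: Sequence,
    kinds: Sequence[str] = ("plsr", "pcr", "svmr"),
    cv_scheme: str = "loo",
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate every (band selection x model kind) cell.

    ``selections`` entries are SelectionResult-like objects (anything with
    ``method`` and ``selected_idx``) or None for the full band axis. Each
    cell restricts the bands, picks the component count by cross-validation
    on the calibration set, refits on the full calibration set, and reports
    calibration, cross-validation, and prediction metrics.
    """
    if len(xpred.wavelengths) != len(xcal.wavelengths) or not np.allclose(
        xpred.wavelengths, xcal.wavelengths
    ):
        raise ContractError("calibration and prediction band axes differ")
    rows = []
    for sel in selections:
        if sel is None:
            idx = np.arange(xcal.n_bands)
            sel_name = ""
        else:
            idx = np.asarray(sel.selected_idx, dtype=int)
            sel_name = sel.method.upper() + "-"
            if idx.size == 0:
                raise ConfigurationError(
                    f"selection {sel.method!r} contains no bands"
                )
        xc = xcal.select_bands(idx)
        xp = xpred.select_bands(idx)
        for kind in kinds:
            if kind in ("plsr", "pcr"):
                cv = cross_validate(kind, xc, ycal, scheme=cv_scheme, seed=seed)
                model = fit(kind, xc, ycal, n_components=cv.best_components, seed=seed)
                pcs: float | int = cv.best_components
            else:
                cv = cross_validate(kind, xc, ycal, scheme=cv_scheme, seed=seed)
                model = fit(kind, xc, ycal, seed=seed)
                pcs = np.nan
            yhat_cal = predict(model, xc)
            yhat_pred = predict(model, xp)
            rows.append(
                {
                    "model": f"{sel_name}{kind.upper()}",
                    "bands": len(idx),
                    "PCs": pcs,
                    "RC2": r_squared(ycal, yhat_cal),
                    "RMSEC": rmse(ycal, yhat_cal),
                    "RCV2": cv.rcv2,
                    "RMSECV": cv.rmsecv,
                    "RP2": r_squared(ypred, yhat_pred),
                    "RMSEP": rmse(ypred, yhat_pred),
                }
            )
    return EvaluationReport(rows)
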