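"""VIF-gated regression and the statistical verification toolkit.

The predictive model is ordinary least squares on the selected features
unless they are multicollinear — any variance inflation factor (VIF) above 5
— in which case ridge regression with a cross-validated penalty is used
instead.  VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing feature j on
the remaining selected features (with intercept).

Verification statistics: mean absolute error between predicted and actual
outcomes, a two-sided paired t-test on their differences, and Cohen's d
computed as |mean_actual - mean_predicted| / SD_actual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import validate_data

from .errors import DegenerateStatisticError

__all__ = [
    "VifReport",
    "vif",
    "VifGatedRegressor",
    "fit_model",
    "mae",
    "cohens_d",
    "cohens_d_from_summary",
    "paired_t",
    "DEFAULT_RIDGE_GRID",
]

logger = logging.getLogger(__name__)

#: Log-spaced ridge penalty grid for cross-validation.
DEFAULT_RIDGE_GRID = np.logspace(-4, 2, 25)

VIF_THRESHOLD = 5.0


@dataclass(frozen=True)
class VifReport:
    """Per-feature variance inflation factors and the multicollinearity flag."""

    features: tuple[str, ...]
    vif_values: tuple[float, ...]
    threshold: float = VIF_THRESHOLD

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(f for f, v in zip(self.features, self.vif_values) if v > self.threshold)

    @property
    def multicollinear(self) -> bool:
        return len(self.flagged) > 0

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "vif": [None if not np.isfinite(v) else float(v) for v in self.vif_values],
            "threshold": self.threshold,
            "flagged": list(self.flagged),
            "multicollinear": self.multicollinear,
        }


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIFs by direct least-squares regression of each column on the rest."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        xj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        if ss_tot == 0.0:
            out[j] = np.inf  # constant column: perfectly 'explained'
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif(table: pd.DataFrame | np.ndarray, features: list[str] | None = None) -> VifReport:
    """Variance inflation factors for a set of feature columns.

    Accepts a feature table plus column names, or a bare 2-D array.
    Perfectly collinear features are reported as ``inf`` and flagged.
    """
    if isinstance(table, pd.DataFrame):
        if features is None:
            raise ValueError("features must be named when passing a DataFrame")
        X = table[list(features)].to_numpy(dtype=float)
        names = tuple(features)
    else:
        X = np.asarray(table, dtype=float)
        names = tuple(features) if features is not None else tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"VIF needs at least {X.shape[1] + 2} rows for {X.shape[1]} features, got {X.shape[0]}"
        )
    return VifReport(features=names, vif_values=tuple(_vif_values(X)))


class VifGatedRegressor(RegressorMixin, BaseEstimator):
    """Linear regression that switches to ridge under multicollinearity.

    At ``fit`` time the VIFs of the (training-centered) features are
    computed; if any exceeds ``vif_threshold`` the model is ridge regression
    with the penalty chosen by cross-validation over ``ridge_grid`` —
    analytic leave-one-out CV by default (``cv=None``), or ``cv``-fold
    K-fold — otherwise ordinary least squares.  A rank-deficient design in
    the linear branch also falls back to ridge (logged).

    Fitted attributes: ``model_type_`` ("linear"/"ridge"), ``coef_``,
    ``intercept_``, ``ridge_lambda_`` (0 for linear), ``vif_report_`` and
    ``feature_means_`` (training means used to center test data).
    """

    def __init__(
        self,
        vif_threshold: float = VIF_THRESHOLD,
        ridge_grid=None,
        cv: int | None = None,
        random_state: int | None = None,
    ):
        self.vif_threshold = vif_threshold
        self.ridge_grid = ridge_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.feature_means_ = X.mean(axis=0)
        Xc = X - self.feature_means_

        if p >= 2 and n >= p + 2:
            values = _vif_values(Xc)
        else:  # VIF undefined; treat as non-collinear unless rank-deficient
            values = np.ones(p)
        self.vif_report_ = VifReport(
            features=tuple(
                str(c) for c in getattr(self, "feature_names_in_", [f"x{i}" for i in range(p)])
            ),
            vif_values=tuple(values),
            threshold=self.vif_threshold,
        )

        use_ridge = self.vif_report_.multicollinear
        if not use_ridge:
            A = np.column_stack([np.ones(n), Xc])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                logger.info("singular design in linear mode; falling back to ridge")
                use_ridge = True

        if use_ridge:
            grid = np.asarray(
                DEFAULT_RIDGE_GRID if self.ridge_grid is None else self.ridge_grid, dtype=float
            )
            if self.cv is None:
                model = RidgeCV(alphas=grid, cv=None).fit(Xc, y)  # analytic LOO-CV
            else:
                kf = KFold(n_splits=min(self.cv, n), shuffle=True, random_state=self.random_state)
                model = RidgeCV(alphas=grid, cv=kf).fit(Xc, y)
            self.coef_ = model.coef_.copy()
            self.intercept_ = float(model.intercept_)
            self.ridge_lambda_ = float(model.alpha_)
            self.model_type_ = "ridge"
        else:
            A = np.column_stack([np.ones(n), Xc])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            self.coef_ = beta[1:]
            self.intercept_ = float(beta[0])
            self.ridge_lambda_ = 0.0
            self.model_type_ = "linear"
        return self

    def predict(self, X):
        X = validate_data(self, X, reset=False)
        return (X - self.feature_means_) @ self.coef_ + self.intercept_


def fit_model(
    table: pd.DataFrame,
    outcome: str,
    features: list[str],
    ridge_grid=None,
    cv_folds: int | None = None,
    seed: int | None = None,
    vif_threshold: float = VIF_THRESHOLD,
) -> VifGatedRegressor:
    """Fit the VIF-gated model on a feature table; thin estimator wrapper."""
    if not features:
        raise ValueError("features must be non-empty")
    model = VifGatedRegressor(
        vif_threshold=vif_threshold, ridge_grid=ridge_grid, cv=cv_folds, random_state=seed
    )
    return model.fit(table[list(features)], table[outcome].to_numpy(dtype=float))


def mae(predicted, actual) -> float:
    """Mean absolute error between predicted and actual series."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {actual.shape}")
    if predicted.size == 0:
        raise ValueError("mae undefined on empty series")
    return float(np.mean(np.abs(predicted - actual)))


def cohens_d(actual, predicted, signed: bool = False) -> float:
    """Cohen's d between actual and predicted values.

    ``(mean_actual - mean_predicted) / SD_actual`` with the sample SD of the
    actual values in the denominator; the absolute value is returned unless
    ``signed=True``.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.size < 2:
        raise DegenerateStatisticError("Cohen's d needs >= 2 actual values")
    sd = float(np.std(actual, ddof=1))
    if sd == 0.0:
        raise DegenerateStatisticError("Cohen's d undefined: actual values have zero SD")
    d = (float(np.mean(actual)) - float(np.mean(predicted))) / sd
    return d if signed else abs(d)


def cohens_d_from_summary(mean_actual: float, mean_predicted: float, sd_actual: float) -> float:
    """Cohen's d from summary statistics, |mu1 - mu2| / sigma1."""
    if sd_actual <= 0:
        raise DegenerateStatisticError("Cohen's d undefined for non-positive SD")
    return abs(mean_actual - mean_predicted) / sd_actual


def paired_t(actual, predicted) -> tuple[float, float]:
    """Two-sided paired t-test on actual - predicted differences."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("paired_t requires equal-length series")
    if actual.size < 3:
        raise ValueError("paired_t needs at least 3 pairs")
    diff = actual - predicted
    if np.std(diff, ddof=1) == 0.0:
        raise DegenerateStatisticError("paired t-test undefined: zero-variance differences")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_rel(actual, predicted)
    return float(res.statistic), float(res.pvalue)
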