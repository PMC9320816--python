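"""Feature ranking: LASSO, elastic net, univariate F-test, regression ReliefF.

Each method is an sklearn-style selector estimator (``fit(X, y)`` +
``transform``) exposing ``scores_`` and ``ranking_``; module-level functions
wrap them to operate on a feature table and return a :class:`SelectionResult`.

Penalty parameterization.  The LASSO objective is the residual sum of
squares plus ``lam * sum(|beta|)``; the elastic net generalizes it to
``RSS + lam * (alpha * ||beta||_1 + (1 - alpha) * ||beta||_2^2 / 2)`` so that
``alpha = 1`` reduces *exactly* to the LASSO at the same ``lam`` and
``alpha = 0`` to ridge.  On an orthonormal design the LASSO solution is the
soft-thresholded least-squares estimate ``sign(b) * max(|b| - lam/2, 0)``.
Internally the penalty is rescaled to scikit-learn's per-sample convention.

Regression ReliefF (RReliefF) scores a feature by contrasting how often it
differs between near neighbours that also differ in the response against how
often it differs regardless of the response.  With per-instance
neighbour weights summing to one, the resulting weights lie in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_regression
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import validate_data

from .registry import FEATURE_NAMES

__all__ = [
    "SelectionResult",
    "LassoSelector",
    "ElasticNetSelector",
    "FTestSelector",
    "RReliefFSelector",
    "lasso_rank",
    "elastic_net_rank",
    "f_test_rank",
    "relieff_rank",
    "selection_frequency",
    "split_xy",
]


@dataclass
class SelectionResult:
    """A ranking of features produced by one selection method."""

    method: str
    ranked_features: list[str]
    scores: dict[str, float]
    tuning: dict = field(default_factory=dict)

    def top(self, m: int) -> list[str]:
        return self.ranked_features[:m]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ranked_features": list(self.ranked_features),
            "scores": {k: float(v) for k, v in self.scores.items()},
            "tuning": self.tuning,
        }


def split_xy(table: pd.DataFrame, outcome: str, features: Sequence[str] | None = None):
    """Extract (X, y, feature_names) from a feature table."""
    names = list(features) if features is not None else [c for c in FEATURE_NAMES if c in table.columns]
    return table[names].to_numpy(dtype=float), table[outcome].to_numpy(dtype=float), names


class _RankedSelector(SelectorMixin, BaseEstimator):
    """Shared plumbing: support mask = top ``n_features_to_select`` of ``ranking_``."""

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[: self.n_features_to_select]] = True
        return mask

    def ranked_feature_names(self):
        names = getattr(
            self, "feature_names_in_", np.array([f"x{i}" for i in range(self.n_features_in_)])
        )
        return [str(names[i]) for i in self.ranking_]


def _solve_lasso(X, y, lam: float) -> tuple[np.ndarray, float]:
    """Minimize RSS + lam * ||beta||_1 (intercept unpenalized)."""
    n = X.shape[0]
    if lam == 0.0:
        Xc = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        return beta[1:], float(beta[0])
    model = Lasso(alpha=lam / (2.0 * n), fit_intercept=True, max_iter=50000, tol=1e-10)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


class LassoSelector(_RankedSelector):
    """L1-penalized linear regression; features ranked by |coefficient|.

    ``lam`` fixes the penalty (RSS-plus-penalty units); when ``None`` it is
    chosen by ``cv``-fold cross-validation minimizing mean squared error over
    a log-spaced grid.  ``standardize=True`` scales features to unit variance
    internally; ``coef_`` is reported back on the original (centered) scale
    but the *ranking* uses the standardized-scale coefficient magnitudes, so
    it is invariant to rescaling any feature column.  Only features with
    nonzero coefficients enter the ranking.
    """

    def __init__(
        self,
        n_features_to_select: int = 10,
        lam: float | None = None,
        lam_grid: Sequence[float] | None = None,
        cv: int = 10,
        standardize: bool = True,
        random_state: int | None = None,
    ):
        self.n_features_to_select = n_features_to_select
        self.lam = lam
        self.lam_grid = lam_grid
        self.cv = cv
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        scale = X.std(axis=0, ddof=0) if self.standardize else np.ones(X.shape[1])
        scale = np.where(scale > 0, scale, 1.0)
        Xs = X / scale
        if self.lam is not None:
            coef, intercept = _solve_lasso(Xs, y, float(self.lam))
            lam_used = float(self.lam)
        else:
            kf = KFold(n_splits=min(self.cv, n), shuffle=True, random_state=self.random_state)
            kwargs = {"cv": kf, "fit_intercept": True, "max_iter": 20000, "tol": 1e-5}
            if self.lam_grid is not None:
                kwargs["alphas"] = np.sort(np.asarray(self.lam_grid, dtype=float))[::-1] / (2.0 * n)
            else:
                kwargs["alphas"] = 60  # grid size; sklearn picks the log-spaced values
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = LassoCV(**kwargs).fit(Xs, y)
            coef, intercept = model.coef_.copy(), float(model.intercept_)
            lam_used = float(model.alpha_) * 2.0 * n
        self.coef_ = coef / scale  # back to the centered-feature scale
        self.intercept_ = intercept
        self.lambda_ = lam_used
        self.scores_ = np.abs(coef)  # standardized scale: rescaling-invariant
        nonzero = np.flatnonzero(self.scores_ > 0)
        if nonzero.size == 0:
            warnings.warn("LASSO shrank every coefficient to zero; empty ranking")
        self.ranking_ = nonzero[np.argsort(-self.scores_[nonzero], kind="stable")]
        return self


class ElasticNetSelector(_RankedSelector):
    """Mixed L1/L2 penalty ``lam * (alpha * L1 + (1 - alpha) * L2^2 / 2)``.

    ``alpha = 1`` is the LASSO, ``alpha = 0`` ridge.  Ranking and tuning as
    in :class:`LassoSelector`.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        n_features_to_select: int = 10,
        lam: float | None = None,
        lam_grid: Sequence[float] | None = None,
        cv: int = 10,
        standardize: bool = True,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_features_to_select = n_features_to_select
        self.lam = lam
        self.lam_grid = lam_grid
        self.cv = cv
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        scale = X.std(axis=0, ddof=0) if self.standardize else np.ones(X.shape[1])
        scale = np.where(scale > 0, scale, 1.0)
        Xs = X / scale
        # Our lam (penalty added to raw RSS) maps to sklearn's per-sample
        # alpha as lam / (2n), with l1_ratio = alpha.
        if self.lam is not None:
            if self.lam == 0.0:
                coef, intercept = _solve_lasso(Xs, y, 0.0)
            else:
                model = ElasticNet(
                    alpha=float(self.lam) / (2.0 * n),
                    l1_ratio=self.alpha,
                    fit_intercept=True,
                    max_iter=50000,
                    tol=1e-10,
                )
                model.fit(Xs, y)
                coef, intercept = model.coef_.copy(), float(model.intercept_)
            lam_used = float(self.lam)
        else:
            kf = KFold(n_splits=min(self.cv, n), shuffle=True, random_state=self.random_state)
            kwargs = {
                "l1_ratio": self.alpha if self.alpha > 0 else 1e-6,
                "cv": kf,
                "fit_intercept": True,
                "max_iter": 20000,
                "tol": 1e-5,
            }
            if self.lam_grid is not None:
                kwargs["alphas"] = np.sort(np.asarray(self.lam_grid, dtype=float))[::-1] / (2.0 * n)
            else:
                kwargs["alphas"] = 60  # grid size; sklearn picks the log-spaced values
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ElasticNetCV(**kwargs).fit(Xs, y)
            coef, intercept = model.coef_.copy(), float(model.intercept_)
            lam_used = float(model.alpha_) * 2.0 * n
        self.coef_ = coef / scale
        self.intercept_ = intercept
        self.lambda_ = lam_used
        self.scores_ = np.abs(coef)  # standardized scale: rescaling-invariant
        nonzero = np.flatnonzero(self.scores_ > 0)
        if nonzero.size == 0:
            warnings.warn("elastic net shrank every coefficient to zero; empty ranking")
        self.ranking_ = nonzero[np.argsort(-self.scores_[nonzero], kind="stable")]
        return self


class FTestSelector(_RankedSelector):
    """Univariate linear-regression F-test per feature.

    Features are ranked by ascending p-value of the slope's F-test, ties
    broken by the larger F statistic.  Zero-variance features get F = 0,
    p = 1 and rank last.
    """

    def __init__(self, n_features_to_select: int = 10):
        self.n_features_to_select = n_features_to_select

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 3:
            raise ValueError("F-test ranking needs at least 3 observations")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = f_regression(X, y, force_finite=True)
        const = X.std(axis=0) == 0
        F = np.where(const, 0.0, F)
        p = np.where(const, 1.0, p)
        self.f_statistic_ = F
        self.pvalues_ = p
        self.scores_ = F
        self.ranking_ = np.lexsort((-F, p))  # ascending p, then descending F
        return self


class RReliefFSelector(_RankedSelector):
    """Regression ReliefF feature weights.

    For every instance, the ``n_neighbors`` nearest neighbours (Manhattan
    distance on min-max-normalized features) are weighted by a rank-based
    exponential decay ``exp(-(rank / sigma)^2)`` normalized to sum to one.
    Accumulating the probabilities of a feature differing, the response
    differing, and both differing over all instances yields the weight

        W[f] = N_dYdF[f] / N_dY  -  (N_dF[f] - N_dYdF[f]) / (n - N_dY)

    which lies in [-1, 1].  Duplicate rows (zero-distance neighbours) are
    legitimate neighbours; a constant response yields all-zero weights.
    """

    def __init__(self, n_neighbors: int = 10, sigma: float = 20.0, n_features_to_select: int = 10):
        self.n_neighbors = n_neighbors
        self.sigma = sigma
        self.n_features_to_select = n_features_to_select

    def fit(self, X, y):
        X = validate_data(self, X, reset=True)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        k = min(self.n_neighbors, n - 1)
        if k < 1:
            raise ValueError("RReliefF needs at least 2 instances")
        span = X.max(axis=0) - X.min(axis=0)
        span = np.where(span > 0, span, 1.0)
        Xn = (X - X.min(axis=0)) / span
        y_span = y.max() - y.min()
        if y_span == 0:
            self.scores_ = np.zeros(p)
            self.ranking_ = np.arange(p)
            return self
        yn = (y - y.min()) / y_span

        D = cdist(Xn, Xn, metric="cityblock")
        np.fill_diagonal(D, np.inf)
        nbr = np.argsort(D, axis=1, kind="stable")[:, :k]
        w = np.exp(-((np.arange(1, k + 1) / self.sigma) ** 2))
        w = w / w.sum()

        n_dy = 0.0
        n_df = np.zeros(p)
        n_dydf = np.zeros(p)
        for i in range(n):
            j = nbr[i]
            dy = np.abs(yn[i] - yn[j])  # (k,)
            df = np.abs(Xn[i][None, :] - Xn[j])  # (k, p), per-feature normalized
            n_dy += float(w @ dy)
            n_df += w @ df
            n_dydf += (w * dy) @ df
        if n_dy == 0.0 or n_dy == n:
            self.scores_ = np.zeros(p)
        else:
            self.scores_ = n_dydf / n_dy - (n_df - n_dydf) / (n - n_dy)
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        return self


_SELECTORS = {
    "lasso": LassoSelector,
    "elastic_net": ElasticNetSelector,
    "f_test": FTestSelector,
    "relieff": RReliefFSelector,
}


def make_selector(method: str, **kwargs) -> _RankedSelector:
    if method not in _SELECTORS:
        raise ValueError(f"unknown selection method {method!r}; choose from {sorted(_SELECTORS)}")
    return _SELECTORS[method](**kwargs)


def _result_from(selector: _RankedSelector, method: str, names: list[str], tuning: dict) -> SelectionResult:
    ranked = [names[i] for i in selector.ranking_]
    if method in ("lasso", "elastic_net"):
        scores = {names[i]: float(selector.scores_[i]) for i in selector.ranking_}
    elif method == "f_test":
        scores = {names[i]: float(selector.pvalues_[i]) for i in range(len(names))}
    else:
        scores = {names[i]: float(selector.scores_[i]) for i in range(len(names))}
    return SelectionResult(method=method, ranked_features=ranked, scores=scores, tuning=tuning)


def lasso_rank(
    table: pd.DataFrame,
    outcome: str,
    lam_grid: Sequence[float] | None = None,
    cv_folds: int = 10,
    seed: int | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Rank features by |LASSO coefficient| at the cross-validated penalty."""
    X, y, names = split_xy(table, outcome)
    sel = LassoSelector(lam_grid=lam_grid, cv=cv_folds, random_state=seed, standardize=standardize)
    sel.fit(X, y)
    return _result_from(sel, "lasso", names, {"lambda": sel.lambda_})


def elastic_net_rank(
    table: pd.DataFrame,
    outcome: str,
    alpha: float = 0.5,
    lam_grid: Sequence[float] | None = None,
    cv_folds: int = 10,
    seed: int | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Rank features by |elastic-net coefficient| (mixing parameter alpha)."""
    X, y, names = split_xy(table, outcome)
    sel = ElasticNetSelector(
        alpha=alpha, lam_grid=lam_grid, cv=cv_folds, random_state=seed, standardize=standardize
    )
    sel.fit(X, y)
    return _result_from(sel, "elastic_net", names, {"lambda": sel.lambda_, "alpha": alpha})


def f_test_rank(table: pd.DataFrame, outcome: str) -> SelectionResult:
    """Rank features by ascending univariate F-test p-value."""
    X, y, names = split_xy(table, outcome)
    sel = FTestSelector().fit(X, y)
    return _result_from(sel, "f_test", names, {})


def relieff_rank(
    table: pd.DataFrame, outcome: str, k_neighbors: int = 10, sigma: float = 20.0
) -> SelectionResult:
    """Rank features by descending regression-ReliefF weight."""
    X, y, names = split_xy(table, outcome)
    sel = RReliefFSelector(n_neighbors=k_neighbors, sigma=sigma).fit(X, y)
    return _result_from(sel, "relieff", names, {"k_neighbors": k_neighbors, "sigma": sigma})


def selection_frequency(
    table: pd.DataFrame,
    outcome: str,
    method: str,
    n_iterations: int = 100,
    train_fraction: float = 0.7,
    seed: int | None = None,
    top_m: int = 10,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    **selector_kwargs,
) -> SelectionResult:
    """Frequency of each feature in the method's top-``top_m`` across
    repeated training splits; ranked by frequency, ties by mean score.

    ``splits`` may supply a pre-generated shared split sequence (the
    validation protocol); otherwise splits are generated from ``seed``.
    """
    from .validation import make_splits  # local: avoid cycle

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if splits is None:
        rng = np.random.default_rng(seed)
        splits = make_splits(len(table), n_iterations, train_fraction, rng)
    X, y, names = split_xy(table, outcome)
    counts = {n: 0 for n in names}
    score_sums = {n: 0.0 for n in names}
    for train_idx, _ in splits[:n_iterations]:
        sel = make_selector(method, **selector_kwargs)
        sel.fit(X[train_idx], y[train_idx])
        top = [names[i] for i in sel.ranking_[:top_m]]
        for rank_pos, name in enumerate(top):
            counts[name] += 1
            score_sums[name] += float(sel.scores_[sel.ranking_[rank_pos]])
    freq = {n: counts[n] / len(splits[:n_iterations]) for n in names}
    mean_score = {n: (score_sums[n] / counts[n]) if counts[n] else 0.0 for n in names}
    order = sorted(names, key=lambda n: (-freq[n], -mean_score[n], names.index(n)))
    ranked = [n for n in order if counts[n] > 0]
    return SelectionResult(
        method=method,
        ranked_features=ranked,
        scores=freq,
        tuning={"n_iterations": n_iterations, "top_m": top_m, "mode": "frequency"},
    )
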